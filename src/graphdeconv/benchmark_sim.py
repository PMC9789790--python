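"""Benchmark protocol: square binning of single-cell-resolution spatial data
into simulated low-resolution spots, plus the RMSE / Jensen-Shannon
divergence scores used to compare predicted and true compositions.

Single-cell imaging platforms (seqFISH+-like, MERFISH-like) resolve every
cell's position, type and expression; binning them on a square grid yields
spots whose true cell-type proportions are known exactly, giving a ground
truth for deconvolution.  Typical square sides for a ~51.5 um-pitch array
are 25.75 (0.5x), 51.5 (1x) and 103 (2x) in the dataset's length unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    CellAnnotation,
    ExpressionMatrix,
    ProportionMatrix,
    SpotCoordinates,
)


@dataclass
class SimulatedSpotSet:
    """Square-binned spots with exact ground-truth composition."""

    expression: ExpressionMatrix  # spots x genes, summed member-cell counts
    coords: SpotCoordinates  # square centers
    truth: ProportionMatrix
    cells_per_spot: list[int]


def bin_cells_to_spots(
    cell_coords: np.ndarray,
    cell_types: CellAnnotation,
    cell_expr: ExpressionMatrix,
    side: float,
) -> SimulatedSpotSet:
    """Bin cells into a square grid anchored at the bounding-box minimum.

    A cell at (x, y) lands in square (floor((x - x_min)/side),
    floor((y - y_min)/side)) — half-open intervals, so a cell exactly on a
    right/top boundary belongs to the next square.  Spot expression is the
    sum of member-cell expression; truth is the member type counts divided
    by the member count; empty squares are dropped.
    """
    if side <= 0:
        raise ValueError("square side must be positive")
    cell_coords = np.asarray(cell_coords, dtype=float)
    n = len(cell_coords)
    if n == 0:
        raise ValueError("no cells to bin")
    if not (n == len(cell_types.cell_ids) == cell_expr.n_obs):
        raise ValueError("coordinates, types and expression must align by cell")

    lo = cell_coords.min(axis=0)
    bins = np.floor((cell_coords - lo) / side).astype(int)
    type_codes = cell_types.type_indices()
    T = cell_types.n_types

    keys = sorted({(int(bx), int(by)) for bx, by in bins})
    key_idx = {k: i for i, k in enumerate(keys)}
    n_spots = len(keys)

    expr = np.zeros((n_spots, cell_expr.n_genes))
    counts = np.zeros((n_spots, T))
    m = np.zeros(n_spots, dtype=int)
    for c in range(n):
        i = key_idx[(int(bins[c, 0]), int(bins[c, 1]))]
        expr[i] += cell_expr.values[c]
        counts[i, type_codes[c]] += 1
        m[i] += 1

    centers = np.array([[lo[0] + (bx + 0.5) * side, lo[1] + (by + 0.5) * side] for bx, by in keys])
    ids = [f"spot_{bx}_{by}" for bx, by in keys]
    return SimulatedSpotSet(
        expression=ExpressionMatrix(expr, ids, list(cell_expr.gene_ids), "st"),
        coords=SpotCoordinates(ids, centers[:, 0], centers[:, 1], pitch_h=side),
        truth=ProportionMatrix(ids, list(cell_types.type_names), counts / m[:, None]),
        cells_per_spot=[int(v) for v in m],
    )


def _aligned(pred: ProportionMatrix, truth: ProportionMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(pred.type_names) != set(truth.type_names):
        raise ValueError("prediction and truth disagree on the cell-type set")
    if len(pred.obs_ids) != len(truth.obs_ids) or set(pred.obs_ids) != set(truth.obs_ids):
        raise ValueError("prediction and truth disagree on the spot set")
    t_col = [truth.type_names.index(t) for t in pred.type_names]
    t_row = {o: i for i, o in enumerate(truth.obs_ids)}
    rows = [t_row[o] for o in pred.obs_ids]
    return pred.values, truth.values[np.ix_(rows, t_col)]


def rmse(
    pred: ProportionMatrix, truth: ProportionMatrix, mode: str = "overall"
) -> float | np.ndarray:
    """Root-mean-square error over all spot x type entries.

    ``mode='per_type'`` returns one RMSE per cell type (column order follows
    ``pred.type_names``).
    """
    p, t = _aligned(pred, truth)
    sq = (p - t) ** 2
    if mode == "overall":
        return float(np.sqrt(sq.mean()))
    if mode == "per_type":
        return np.sqrt(sq.mean(axis=0))
    raise ValueError(f"unknown mode {mode!r}")


def jsd(pred: ProportionMatrix, truth: ProportionMatrix) -> float:
    """Mean per-spot Jensen-Shannon divergence, log base 2 (range [0, 1]).

    JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m = (p+q)/2 and 0*log0 := 0.
    """
    p, q = _aligned(pred, truth)
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = a * (np.log2(a) - np.log2(b))
        return np.where(a > 0, term, 0.0).sum(axis=1)

    per_spot = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    return float(per_spot.mean())
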