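"""Fully synthetic reference and spatial datasets.

Emulates the statistical structure the deconvolution method assumes:

* a reference of single cells with cell-type-specific marker genes
  (negative-binomial counts, disjoint marker blocks with a configurable
  fold-change);
* dropout imposed as independent Bernoulli zeroing with probability
  1 - mu_g/(mu_g + K_true) per gene, so empirical dropout rates sit on the
  Michaelis-Menten curve with constant ``K_true`` — parameter recovery by
  the selection module is then a fair test;
* planar tissues with spatially clustered types (vertical-band layout,
  mirroring layered cortex), a smooth gradient, or a spatially homogeneous
  control;
* a spot-array view on a staggered lattice where each interior spot has its
  four neighbors at the diagonal offsets (+/- h/2, +/- h/2), so spatial-edge
  detection is exercised exactly.

All outputs use the standard in-memory containers and can be written with
the io module, so fixtures double as pipeline inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io_formats import (
    CellAnnotation,
    ExpressionMatrix,
    ProportionMatrix,
    SpotCoordinates,
)

_NB_SIZE = 2.0  # negative-binomial dispersion (fixed for realism, not a knob)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a small but non-trivial dataset."""

    n_types: int = 3
    n_genes: int = 200
    n_cells: int = 600
    markers_per_type: int = 20
    marker_fold: float = 8.0
    K_true: float = 2.0
    base_mean: float = 1.0  # scale of the lognormal base expression
    spatial_layout: str = "blocks"  # blocks | gradient | random
    grid_rows: int = 8
    grid_cols: int = 8
    pitch_h: float = 100.0
    n_tissue_cells: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_types, self.n_genes, self.n_cells, self.markers_per_type) < 1:
            raise ValueError("counts must be >= 1")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("marker blocks exceed the gene count")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.spatial_layout not in ("blocks", "gradient", "random"):
            raise ValueError(f"unknown spatial_layout {self.spatial_layout!r}")


@dataclass
class SyntheticTissue:
    """Single-cell-resolution tissue: positions, types and expression."""

    coords: np.ndarray  # n x 2
    annotation: CellAnnotation
    expression: ExpressionMatrix


def _type_means(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-type, per-gene expected expression with disjoint marker blocks."""
    base = rng.lognormal(mean=np.log(cfg.base_mean), sigma=1.0, size=cfg.n_genes)
    means = np.tile(base, (cfg.n_types, 1))
    for t in range(cfg.n_types):
        block = slice(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type)
        means[t, block] *= cfg.marker_fold
    return means


def marker_gene_ids(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Marker gene ids per type (by construction, blocks of the gene list)."""
    return {
        f"type_{t}": [
            f"gene_{j}"
            for j in range(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type)
        ]
        for t in range(cfg.n_types)
    }


def _nb_counts(rng: np.random.Generator, mu: np.ndarray) -> np.ndarray:
    # NB with fixed size: p = size/(size + mu)
    p = _NB_SIZE / (_NB_SIZE + mu)
    return rng.negative_binomial(_NB_SIZE, p)


def simulate_reference(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Annotated single-cell reference with marker structure and dropout.

    Counts are negative binomial around the type-specific means; each entry
    is then independently zeroed with probability 1 - mu_g/(mu_g + K_true)
    where mu_g is the gene's grand mean across types, so the gene-level
    dropout/mean relation follows the Michaelis-Menten curve at K_true.
    Cells are balanced across types.
    """
    rng = np.random.default_rng(cfg.seed)
    means = _type_means(cfg, rng)
    types = np.arange(cfg.n_cells) % cfg.n_types
    counts = _nb_counts(rng, means[types])

    grand_mean = means.mean(axis=0)
    p_drop = 1.0 - grand_mean / (grand_mean + cfg.K_true)
    keep = rng.random(counts.shape) >= p_drop[None, :]
    counts = counts * keep

    cell_ids = [f"cell_{i}" for i in range(cfg.n_cells)]
    gene_ids = [f"gene_{j}" for j in range(cfg.n_genes)]
    type_names = [f"type_{t}" for t in range(cfg.n_types)]
    ann = CellAnnotation(cell_ids, [type_names[t] for t in types], type_names)
    return ExpressionMatrix(counts.astype(float), cell_ids, gene_ids, "scrna"), ann


def simulate_spatial_tissue(
    cfg: SyntheticConfig, ref: tuple[ExpressionMatrix, CellAnnotation]
) -> SyntheticTissue:
    """Place ``n_tissue_cells`` cells on a rectangle with the chosen layout.

    * ``blocks``: the rectangle splits into n_types vertical bands; each
      band draws 90% of its cells from its own type (spatially clustered
      types, as in layered cortex) and 10% uniformly from the others.
    * ``gradient``: type probability shifts linearly left-to-right.
    * ``random``: types spatially homogeneous.

    Expression vectors are resampled from reference cells of the assigned
    type, so the tissue and the reference share the same per-type profile.
    """
    sc, ann = ref
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_tissue_cells
    width = cfg.grid_cols * cfg.pitch_h
    height = cfg.grid_rows * cfg.pitch_h
    coords = np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])

    T = cfg.n_types
    if cfg.spatial_layout == "blocks":
        band = np.minimum((coords[:, 0] / width * T).astype(int), T - 1)
        types = band.copy()
        flip = rng.random(n) < 0.10
        types[flip] = rng.integers(0, T, size=int(flip.sum()))
    elif cfg.spatial_layout == "gradient":
        frac = coords[:, 0] / width
        probs = np.stack([np.linspace(1, 0, T)[t] * (1 - frac) + np.linspace(0, 1, T)[t] * frac for t in range(T)], axis=1)
        probs /= probs.sum(axis=1, keepdims=True)
        types = np.array([rng.choice(T, p=p) for p in probs])
    else:  # random
        types = rng.integers(0, T, size=n)

    type_codes = ann.type_indices()
    pools = [np.flatnonzero(type_codes == t) for t in range(T)]
    source = np.array([rng.choice(pools[t]) for t in types])
    expr = sc.values[source]

    cell_ids = [f"tcell_{i}" for i in range(n)]
    annotation = CellAnnotation(
        cell_ids, [ann.type_names[t] for t in types], list(ann.type_names)
    )
    return SyntheticTissue(
        coords=coords,
        annotation=annotation,
        expression=ExpressionMatrix(expr.copy(), cell_ids, list(sc.gene_ids), "st"),
    )


def staggered_lattice(
    rows: int, cols: int, h: float
) -> tuple[np.ndarray, list[str]]:
    """Spot centers on a staggered lattice with pitch h.

    Rows are h/2 apart vertically and alternate rows are offset by h/2, so
    each interior spot's four nearest neighbors sit exactly at
    (+/- h/2, +/- h/2).
    """
    if rows < 2 or cols < 2:
        raise ValueError("lattice must be at least 2 x 2")
    pts, ids = [], []
    for r in range(rows):
        x0 = (h / 2) if (r % 2) else 0.0
        for c in range(cols):
            pts.append([x0 + c * h, r * h / 2])
            ids.append(f"spot_r{r}c{c}")
    return np.asarray(pts), ids


def make_visium_like(
    cfg: SyntheticConfig, tissue: SyntheticTissue
) -> tuple[ExpressionMatrix, SpotCoordinates, ProportionMatrix]:
    """Aggregate the tissue into spots on a staggered lattice.

    Each spot sums the expression of its 10-20 nearest cells (count drawn
    per spot, matching typical spot occupancy) and records the exact type
    proportions of those cells as truth.  Cells may contribute to more than
    one spot when spots are close; each spot's truth refers to its own
    member set.
    """
    if cfg.grid_rows < 2 or cfg.grid_cols < 2:
        raise ValueError("grid too small (< 2 x 2)")
    rng = np.random.default_rng(cfg.seed + 2)
    pts, ids = staggered_lattice(cfg.grid_rows, cfg.grid_cols, cfg.pitch_h)
    # center the lattice on the tissue rectangle
    pts = pts - pts.mean(axis=0) + tissue.coords.mean(axis=0)

    nn = NearestNeighbors(n_neighbors=min(20, len(tissue.coords))).fit(tissue.coords)
    _, neigh = nn.kneighbors(pts)
    type_codes = tissue.annotation.type_indices()
    T = tissue.annotation.n_types

    expr = np.zeros((len(pts), tissue.expression.n_genes))
    truth = np.zeros((len(pts), T))
    m_max = neigh.shape[1]
    m_min = min(10, m_max)
    for i in range(len(pts)):
        m = int(rng.integers(m_min, m_max + 1))
        members = neigh[i, :m]
        expr[i] = tissue.expression.values[members].sum(axis=0)
        counts = np.bincount(type_codes[members], minlength=T)
        truth[i] = counts / m

    st = ExpressionMatrix(expr, ids, list(tissue.expression.gene_ids), "st")
    coords = SpotCoordinates(ids, pts[:, 0], pts[:, 1], pitch_h=cfg.pitch_h)
    props = ProportionMatrix(ids, list(tissue.annotation.type_names), truth)
    return st, coords, props
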