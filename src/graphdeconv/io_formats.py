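"""Readers and writers for the delimited matrix/coordinate/annotation formats.

Supported on-disk layouts:

* dense CSV/TSV with a header row of gene ids and one row per observation,
  first column = observation id;
* Matrix Market (MTX) triplet with plain-text ``genes``/``barcodes`` sidecar
  files next to the matrix;
* coordinates / annotations / proportions as delimited tables.

All science-free: validation and orientation handling only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

Modality = Literal["st", "scrna", "pseudo"]

#: fixed decimal format with >= 9 significant digits so round-trips are testable
_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared layout."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Observations x genes matrix of non-negative finite values.

    ``modality`` records what the rows are: real spatial spots (``st``),
    annotated single cells (``scrna``) or synthesized pseudo-spots
    (``pseudo``).
    """

    values: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]
    modality: Modality = "st"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.obs_ids = _check_unique(self.obs_ids, "observation ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if self.values.shape != (len(self.obs_ids), len(self.gene_ids)):
            raise ValidationError(
                f"shape {self.values.shape} != ({len(self.obs_ids)}, {len(self.gene_ids)})"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("negative expression values")

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes``, in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes not present: {missing[:5]}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols], list(self.obs_ids), list(genes), self.modality
        )


@dataclass
class SpotCoordinates:
    """Planar (x, y) positions, one per spot, in the same unit as the pitch."""

    obs_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    pitch_h: float | None = None

    def __post_init__(self) -> None:
        self.obs_ids = _check_unique(self.obs_ids, "spot ids")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.obs_ids) == len(self.x) == len(self.y)):
            raise ValidationError("obs_ids, x, y must have equal length")
        if self.x.size and not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("non-finite coordinates")
        if self.pitch_h is not None and self.pitch_h <= 0:
            raise ValidationError("pitch_h must be positive")

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class CellAnnotation:
    """Per-cell categorical cell-type labels over an ordered type vocabulary."""

    cell_ids: list[str]
    cell_type: list[str]
    type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.cell_type = [str(t) for t in self.cell_type]
        if len(self.cell_ids) != len(self.cell_type):
            raise ValidationError("cell_ids and cell_type must have equal length")
        if not self.type_names:
            self.type_names = sorted(set(self.cell_type))
        self.type_names = _check_unique(self.type_names, "type names")
        unknown = set(self.cell_type) - set(self.type_names)
        if unknown:
            raise ValidationError(f"cell types outside vocabulary: {sorted(unknown)[:5]}")
        if len(self.type_names) < 2:
            raise ValidationError("need at least 2 cell types")

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def type_indices(self) -> np.ndarray:
        """Integer codes into ``type_names``, one per cell."""
        lut = {t: i for i, t in enumerate(self.type_names)}
        return np.array([lut[t] for t in self.cell_type], dtype=int)


@dataclass
class ProportionMatrix:
    """Per-observation cell-type composition; rows sum to 1."""

    obs_ids: list[str]
    type_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.obs_ids = _check_unique(self.obs_ids, "observation ids")
        self.type_names = _check_unique(self.type_names, "type names")
        self.values = np.asarray(self.values, dtype=float).reshape(
            len(self.obs_ids), len(self.type_names)
        )
        if self.values.size:
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
                raise ValidationError("proportions outside [0, 1]")
            rowsums = self.values.sum(axis=1)
            if not np.allclose(rowsums, 1.0, atol=1e-6):
                bad = np.flatnonzero(~np.isclose(rowsums, 1.0, atol=1e-6))
                raise ValidationError(
                    f"rows do not sum to 1 (first offender: {self.obs_ids[bad[0]]}, "
                    f"sum={rowsums[bad[0]]:.6g})"
                )

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)


# ---------------------------------------------------------------------------
# readers


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _read_sidecar(path: Path) -> list[str]:
    # first whitespace-delimited token per line (10x-style sidecars may carry
    # extra columns such as gene symbols)
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(line.split("\t")[0].split(",")[0])
    return out


def _find_sidecar(mtx_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for ext in (".tsv", ".txt", ".csv"):
            cand = mtx_path.with_name(stem + ext)
            if cand.exists():
                return cand
    raise FormatError(
        f"no sidecar file {stems} next to {mtx_path} (tried .tsv/.txt/.csv)"
    )


def read_expression_matrix(
    path: str | Path,
    format_hint: Literal["auto", "dense_csv", "mtx_triplet"] = "auto",
    modality: Modality = "st",
    orientation: Literal["auto", "obs_by_gene", "gene_by_obs"] = "auto",
) -> ExpressionMatrix:
    """Read an expression matrix, normalizing orientation to observations x genes.

    For MTX triplets the gene/barcode sidecar files (``genes.*`` /
    ``features.*`` and ``barcodes.*``) must sit next to the matrix.  With
    ``orientation='auto'`` the stored orientation is inferred by matching the
    sidecar lengths against the declared dimensions; an ambiguous square
    matrix defaults to genes x observations (the common MTX convention)
    with a logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint == "auto":
        format_hint = "mtx_triplet" if path.suffix == ".mtx" else "dense_csv"

    if format_hint == "mtx_triplet":
        mat = scipy.io.mmread(path)
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        genes = _read_sidecar(_find_sidecar(path, ("genes", "features")))
        barcodes = _read_sidecar(_find_sidecar(path, ("barcodes", "cells", "spots")))
        nr, nc = dense.shape
        if orientation == "auto":
            if (len(genes), len(barcodes)) == (nr, nc) and nr != nc:
                orientation = "gene_by_obs"
            elif (len(barcodes), len(genes)) == (nr, nc) and nr != nc:
                orientation = "obs_by_gene"
            elif (len(genes), len(barcodes)) == (nr, nc):
                orientation = "gene_by_obs"
                logger.info("square MTX %s: assuming genes x observations", path)
            else:
                raise FormatError(
                    f"sidecar lengths (genes={len(genes)}, barcodes={len(barcodes)}) "
                    f"match neither orientation of matrix {dense.shape}"
                )
        if orientation == "gene_by_obs":
            dense = dense.T
            if (nc, nr) != (len(barcodes), len(genes)):
                raise FormatError(
                    f"matrix {('%d x %d' % (nr, nc))} does not match sidecars "
                    f"(genes={len(genes)}, barcodes={len(barcodes)})"
                )
        elif (nr, nc) != (len(barcodes), len(genes)):
            raise FormatError(
                f"matrix {('%d x %d' % (nr, nc))} does not match sidecars "
                f"(genes={len(genes)}, barcodes={len(barcodes)})"
            )
        if dense.size and dense.min() < 0:
            raise ValidationError(f"negative entries in {path}")
        return ExpressionMatrix(dense, barcodes, genes, modality)

    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    obs_ids = [str(i) for i in df.index]
    gene_ids = [str(c) for c in df.columns]
    if orientation == "gene_by_obs":
        values, obs_ids, gene_ids = values.T, gene_ids, obs_ids
    if values.size and np.nanmin(values) < 0:
        raise ValidationError(f"negative entries in {path}")
    return ExpressionMatrix(values, obs_ids, gene_ids, modality)


def read_coordinates(path: str | Path, pitch_h: float | None = None) -> SpotCoordinates:
    """Read a delimited table with id, x, y columns (named or positional)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        id_col = next(
            (cols[c] for c in ("id", "spot", "spot_id", "barcode", "obs_id") if c in cols),
            df.columns[0],
        )
        x, y = df[cols["x"]], df[cols["y"]]
        ids = df[id_col]
    elif df.shape[1] >= 3:
        ids, x, y = df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]
    else:
        raise FormatError(f"{path}: need id, x, y columns")
    try:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric coordinates") from exc
    return SpotCoordinates([str(i) for i in ids], x, y, pitch_h)


def read_annotations(path: str | Path) -> CellAnnotation:
    """Read per-cell labels from a two-column delimited table (id, cell_type)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need id and cell_type columns")
    return CellAnnotation(
        [str(i) for i in df.iloc[:, 0]], [str(t) for t in df.iloc[:, 1]]
    )


def read_proportions(path: str | Path) -> ProportionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    return ProportionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


# ---------------------------------------------------------------------------
# writers


def write_proportions(props: ProportionMatrix, path: str | Path) -> None:
    """Write one row per spot, columns = type names; round-trips within 1e-9."""
    df = pd.DataFrame(props.values, index=props.obs_ids, columns=props.type_names)
    df.index.name = "spot"
    df.to_csv(path, float_format=_FLOAT_FMT)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.obs_ids, columns=m.gene_ids)
    df.index.name = "obs"
    df.to_csv(path, float_format=_FLOAT_FMT)


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> None:
    pd.DataFrame({"id": coords.obs_ids, "x": coords.x, "y": coords.y}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_annotations(ann: CellAnnotation, path: str | Path) -> None:
    pd.DataFrame({"cell": ann.cell_ids, "cell_type": ann.cell_type}).to_csv(
        path, index=False
    )


def intersect_genes(a: ExpressionMatrix, b: ExpressionMatrix) -> list[str]:
    """Shared gene ids, matched exactly after case-folding + whitespace strip.

    No symbol/alias resolution is attempted.  Order follows ``a``.
    """
    norm = lambda g: g.strip().casefold()
    b_set = {norm(g) for g in b.gene_ids}
    return [g for g in a.gene_ids if norm(g) in b_set]
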