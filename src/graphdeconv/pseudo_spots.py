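"""Pseudo-spot synthesis and shared library-size normalization.

A pseudo-spot mimics a multi-cell capture spot: m annotated single cells are
drawn and their expression vectors averaged, so the spot carries an exact
composition label (count of each type / m).  These labelled spots supply the
supervision for semi-supervised deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import CellAnnotation, ExpressionMatrix, ProportionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PseudoSpotSet:
    """Synthesized spots with exact ground-truth composition labels."""

    expression: ExpressionMatrix  # n_p x genes, modality="pseudo"
    labels: ProportionMatrix  # n_p x T
    m_per_spot: list[int]


def generate_pseudo_spots(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    n_spots: int,
    m_min: int = 10,
    m_max: int = 20,
    seed: int = 0,
) -> PseudoSpotSet:
    """Mix m ~ U{m_min..m_max} cells per spot; expression = cellwise mean.

    Cells are sampled uniformly without replacement within a spot and with
    replacement across spots.  Label for type c is m_c / m, so every label
    row sums to 1 exactly.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if m_min > m_max:
        raise ValueError(f"m_min ({m_min}) > m_max ({m_max})")
    if m_max > sc.n_obs:
        raise ValueError(f"m_max ({m_max}) exceeds number of cells ({sc.n_obs})")
    if sc.obs_ids != ann.cell_ids:
        raise ValueError("expression rows and annotations must list the same cells")

    rng = np.random.default_rng(seed)
    type_codes = ann.type_indices()
    T = ann.n_types

    expr = np.empty((n_spots, sc.n_genes))
    labels = np.empty((n_spots, T))
    ms: list[int] = []
    for i in range(n_spots):
        m = int(rng.integers(m_min, m_max + 1))
        members = rng.choice(sc.n_obs, size=m, replace=False)
        expr[i] = sc.values[members].mean(axis=0)
        counts = np.bincount(type_codes[members], minlength=T)
        labels[i] = counts / m
        ms.append(m)

    ids = [f"pseudo_{i}" for i in range(n_spots)]
    return PseudoSpotSet(
        expression=ExpressionMatrix(expr, ids, list(sc.gene_ids), "pseudo"),
        labels=ProportionMatrix(ids, list(ann.type_names), labels),
        m_per_spot=ms,
    )


def normalize_library(
    m: ExpressionMatrix, size_factor: float = 10_000.0
) -> ExpressionMatrix:
    """Scale each observation so its total equals ``size_factor``.

    Zero-sum rows cannot be normalized; they are dropped with a logged
    warning naming the offending ids.  Idempotent.
    """
    sums = m.values.sum(axis=1)
    zero = sums == 0
    if zero.all():
        raise ValueError("all observations have zero total counts")
    if zero.any():
        dropped = [m.obs_ids[i] for i in np.flatnonzero(zero)]
        logger.warning(
            "normalize_library: dropping %d zero-sum observations: %s",
            len(dropped),
            dropped[:10],
        )
    keep = ~zero
    values = m.values[keep] * (size_factor / sums[keep][:, None])
    return ExpressionMatrix(
        values,
        [m.obs_ids[i] for i in np.flatnonzero(keep)],
        list(m.gene_ids),
        m.modality,
    )
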