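"""Dropout-based informative-gene selection.

Sparse count data exhibit "dropout": a transcript is expressed but not
captured, producing excess zeros.  Across genes, the dropout rate P and the
mean expression E follow a Michaelis-Menten saturation curve

    P = 1 - E / (E + K),

with a single global constant ``K_M`` describing the technical baseline.
Genes whose gene-specific constant ``K_i`` (the K solving the curve exactly
for that gene's observed E and P) significantly exceeds ``K_M`` drop out more
often than their expression level predicts — a signature of bimodal,
cell-type-restricted expression — and are selected as informative features.

The global ``K_M`` is fit by maximum likelihood, modelling each gene's zero
count among ``n_obs`` observations as Binomial(n_obs, 1 - E/(E + K_M)).
Per-gene significance is a right-tailed test of log K_i > log K_M with the
binomial standard error of P propagated through K(P) = E*P/(1-P) on the log
scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneDropoutStats:
    """Per-gene mean expression, dropout rate and fitted curve constants."""

    gene_id: str
    E: float
    P: float
    K_i: float | None = None
    se_logK: float | None = None
    p_value: float | None = None
    q_value: float | None = None


@dataclass
class GlobalDropoutFit:
    """Maximum-likelihood global Michaelis-Menten constant."""

    K_M: float
    log_likelihood: float
    n_genes_used: int


def compute_dropout_stats(m: ExpressionMatrix) -> list[GeneDropoutStats]:
    """Per-gene dropout rate P = #zeros/#obs and mean expression E.

    Expects library-size-normalized values (the curve relates dropout to an
    expression magnitude that must be comparable across observations).
    """
    if m.n_obs < 2:
        raise ValueError("need at least 2 observations for dropout statistics")
    P = (m.values == 0).mean(axis=0)
    E = m.values.mean(axis=0)
    return [
        GeneDropoutStats(g, float(E[j]), float(P[j])) for j, g in enumerate(m.gene_ids)
    ]


def estimate_gene_K(E: float, P: float) -> float:
    """Invert the dropout curve for one gene: K_i = E*P/(1-P).

    Undefined at P = 1 (such genes are excluded from fitting and testing).
    """
    if not 0 <= P < 1:
        raise ValueError(f"P must be in [0, 1), got {P}")
    if E < 0:
        raise ValueError(f"E must be non-negative, got {E}")
    return E * P / (1.0 - P)


def _usable(stats: list[GeneDropoutStats]) -> list[GeneDropoutStats]:
    return [s for s in stats if 0.0 < s.P < 1.0 and s.E > 0]


def fit_global_KM(stats: list[GeneDropoutStats], n_obs: int) -> GlobalDropoutFit:
    """Fit K_M by 1-D maximum likelihood over log K_M.

    Each gene's zero count z_g = P_g * n_obs is Binomial(n_obs, p_g) with
    p_g = 1 - E_g/(E_g + K_M) = K_M/(E_g + K_M); the binomial coefficients
    are constant in K_M and dropped.  Genes with P in {0, 1} carry no
    interior information about K_M and are excluded (logged).
    """
    usable = _usable(stats)
    n_excluded = len(stats) - len(usable)
    if n_excluded:
        logger.info("fit_global_KM: excluded %d genes with P in {0,1} or E=0", n_excluded)
    if not usable:
        raise ValueError(
            "global fit impossible: every gene has dropout rate 0 or 1 "
            "(optimum at the boundary)"
        )
    E = np.array([s.E for s in usable])
    z = np.array([s.P for s in usable]) * n_obs  # zero counts

    def neg_ll(logK: float) -> float:
        K = math.exp(logK)
        p = K / (E + K)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(z * np.log(p) + (n_obs - z) * np.log1p(-p)))

    res = minimize_scalar(neg_ll, bounds=(math.log(1e-6), math.log(1e6)), method="bounded")
    K_M = float(math.exp(res.x))
    return GlobalDropoutFit(K_M=K_M, log_likelihood=-float(res.fun), n_genes_used=len(usable))


def test_gene_significance(
    stats: list[GeneDropoutStats],
    fit: GlobalDropoutFit,
    n_obs: int,
    two_sided: bool = False,
) -> list[GeneDropoutStats]:
    """Fill K_i, se_logK, p and BH q per gene (genes with P in {0,1} get NaN p).

    The statistic is z = (log K_i - log K_M)/se_logK with
    se_logK = 1/sqrt(n_obs * P * (1-P)) (delta method through K(P) = E*P/(1-P)
    on the log scale), referred to a t distribution with n_obs - 1 df.
    Right-tailed by default: excess dropout is what marks a gene informative.
    """
    if n_obs < 3:
        raise ValueError("significance testing needs at least 3 observations")
    logKM = math.log(fit.K_M)
    testable: list[int] = []
    for idx, s in enumerate(stats):
        if not (0.0 < s.P < 1.0 and s.E > 0):
            s.K_i = 0.0 if s.P == 0.0 else None
            s.p_value = s.q_value = math.nan
            continue
        s.K_i = estimate_gene_K(s.E, s.P)
        se_P = math.sqrt(s.P * (1 - s.P) / n_obs)
        s.se_logK = se_P / (s.P * (1 - s.P))
        zstat = (math.log(s.K_i) - logKM) / s.se_logK
        if two_sided:
            s.p_value = float(2 * t_dist.sf(abs(zstat), n_obs - 1))
        else:
            s.p_value = float(t_dist.sf(zstat, n_obs - 1))
        testable.append(idx)
    if testable:
        pvals = [stats[i].p_value for i in testable]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for i, q in zip(testable, qvals):
            stats[i].q_value = float(q)
    return stats


def _rank_key(s: GeneDropoutStats):
    # ascending p, ties by descending K_i, then gene id — deterministic
    p = s.p_value if s.p_value is not None and not math.isnan(s.p_value) else math.inf
    k = s.K_i if s.K_i is not None else -math.inf
    return (p, -k, s.gene_id)


def select_dropout_genes(
    st_stats: list[GeneDropoutStats],
    sc_stats: list[GeneDropoutStats],
    top_k: int = 2000,
) -> list[str]:
    """Intersect the per-dataset top-k significant genes.

    Each dataset is ranked by ascending p-value (ties by descending K_i, then
    gene id); the intersection of the two top-k sets is returned ordered by
    the spatial dataset's p-value.  Both matrices should subsequently be
    subset to this list.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    st_top = [s.gene_id for s in sorted(st_stats, key=_rank_key)[:top_k]]
    sc_top = {s.gene_id for s in sorted(sc_stats, key=_rank_key)[:top_k]}
    selected = [g for g in st_top if g in sc_top]
    if not selected:
        raise ValueError(
            f"empty intersection of top-{top_k} gene sets; raise top_k or check "
            "that the datasets share gene identifiers"
        )
    return selected


def export_stats_tsv(stats: list[GeneDropoutStats], path) -> None:
    """Write per-gene statistics as TSV for inspection."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "gene": s.gene_id,
                "E": s.E,
                "P": s.P,
                "K_i": s.K_i,
                "p_value": s.p_value,
                "q_value": s.q_value,
            }
            for s in stats
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
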