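import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from graphdeconv import dropout_selection as ds
from graphdeconv.dropout_selection import GeneDropoutStats
from graphdeconv.io_formats import ExpressionMatrix


class TestDropoutStats:
    @pytest.mark.parametrize(
        "column, P, E",
        [
            ([0, 0, 0, 0], 1.0, 0.0),
            ([2, 0, 0, 2], 0.5, 1.0),
            ([1, 2, 3, 4], 0.0, 2.5),
        ],
    )
    def test_rate_and_mean(self, column, P, E):
        m = ExpressionMatrix(np.array(column)[:, None], [f"o{i}" for i in range(4)], ["g"])
        (s,) = ds.compute_dropout_stats(m)
        assert s.P == P and s.E == E

    def test_needs_two_observations(self):
        m = ExpressionMatrix(np.ones((1, 1)), ["o"], ["g"])
        with pytest.raises(ValueError):
            ds.compute_dropout_stats(m)


class TestGeneK:
    @pytest.mark.parametrize(
        "E, P, K",
        [(1.0, 0.5, 1.0), (3.0, 0.25, 1.0), (5.0, 0.0, 0.0)],
    )
    def test_known_inversions(self, E, P, K):
        assert ds.estimate_gene_K(E, P) == pytest.approx(K, abs=1e-15)

    def test_P_of_one_is_undefined(self):
        with pytest.raises(ValueError):
            ds.estimate_gene_K(1.0, 1.0)

    @settings(max_examples=100, deadline=None)
    @given(E=st.floats(1e-6, 1e4), P=st.floats(1e-6, 1 - 1e-6))
    def test_curve_inversion_round_trip(self, E, P):
        """Plugging K_i back into the saturation curve recovers P to 1e-12."""
        K = ds.estimate_gene_K(E, P)
        assert 1 - E / (E + K) == pytest.approx(P, abs=1e-12)


def _curve_exact_stats(K_true, n_obs, E_values):
    """Genes whose zero counts sit exactly on the curve (rounded to counts)."""
    out = []
    for i, E in enumerate(E_values):
        zeros = round(n_obs * (1 - E / (E + K_true)))
        out.append(GeneDropoutStats(f"g{i}", E=E, P=zeros / n_obs))
    return out


def _grid_search_KM(stats, n_obs, grid):
    """Independent oracle: direct binomial log-likelihood over a K grid."""
    best, best_ll = None, -np.inf
    for K in grid:
        ll = 0.0
        for s in stats:
            p = K / (s.E + K)
            ll += binom.logpmf(round(s.P * n_obs), n_obs, p)
        if ll > best_ll:
            best, best_ll = K, ll
    return best


class TestGlobalFit:
    def test_recovers_K_on_curve_exact_data(self):
        stats = _curve_exact_stats(2.0, 1000, [0.5, 1, 2, 4, 8])
        fit = ds.fit_global_KM(stats, 1000)
        assert fit.K_M == pytest.approx(2.0, rel=0.05)
        oracle = _grid_search_KM(stats, 1000, np.geomspace(0.01, 100, 4000))
        assert fit.K_M == pytest.approx(oracle, rel=0.01)

    def test_single_gene_inverts_exactly(self):
        fit = ds.fit_global_KM([GeneDropoutStats("g", E=1.0, P=0.5)], 10)
        assert fit.K_M == pytest.approx(1.0, rel=1e-4)

    def test_duplicated_gene_leaves_argmax_unchanged(self):
        one = ds.fit_global_KM([GeneDropoutStats("g", E=1.0, P=0.5)], 10)
        two = ds.fit_global_KM(
            [GeneDropoutStats("g1", E=1.0, P=0.5), GeneDropoutStats("g2", E=1.0, P=0.5)],
            10,
        )
        assert two.K_M == pytest.approx(one.K_M, rel=1e-6)

    def test_gene_order_invariance(self):
        stats = _curve_exact_stats(2.0, 500, [0.5, 1, 2, 4, 8])
        a = ds.fit_global_KM(stats, 500).K_M
        b = ds.fit_global_KM(stats[::-1], 500).K_M
        assert a == pytest.approx(b, rel=1e-10)

    def test_all_degenerate_rates_is_an_error(self):
        with pytest.raises(ValueError):
            ds.fit_global_KM([GeneDropoutStats("g", E=1.0, P=0.0)], 10)


class TestSignificance:
    def test_gene_at_global_K_has_p_half(self):
        fit = ds.GlobalDropoutFit(K_M=1.0, log_likelihood=0.0, n_genes_used=1)
        stats = [GeneDropoutStats("g", E=1.0, P=0.5)]  # K_i = 1 = K_M
        ds.test_gene_significance(stats, fit, n_obs=100)
        assert stats[0].p_value == pytest.approx(0.5, abs=1e-12)

    def test_hugely_inflated_K_is_significant(self):
        fit = ds.GlobalDropoutFit(K_M=0.01, log_likelihood=0.0, n_genes_used=1)
        # K_i = 1, i.e. 100x the global constant; se_logK ~ 0.1 at this n
        stats = [GeneDropoutStats("g", E=1.0, P=0.5)]
        ds.test_gene_significance(stats, fit, n_obs=400)
        assert stats[0].p_value < 1e-10

    def test_bh_q_dominates_p(self, rng):
        n_obs = 200
        stats = [
            GeneDropoutStats(f"g{i}", E=float(E), P=float(P))
            for i, (E, P) in enumerate(
                zip(rng.uniform(0.5, 5, 50), rng.uniform(0.05, 0.95, 50))
            )
        ]
        fit = ds.fit_global_KM(stats, n_obs)
        ds.test_gene_significance(stats, fit, n_obs)
        for s in stats:
            assert 0 <= s.p_value <= 1
            assert s.q_value >= s.p_value - 1e-12

    def test_refuses_tiny_samples(self):
        fit = ds.GlobalDropoutFit(K_M=1.0, log_likelihood=0.0, n_genes_used=1)
        with pytest.raises(ValueError):
            ds.test_gene_significance([GeneDropoutStats("g", 1.0, 0.5)], fit, n_obs=2)


class TestSelection:
    def _ranked_stats(self, pvals):
        return [
            GeneDropoutStats(g, E=1.0, P=0.5, K_i=1.0, p_value=p)
            for g, p in pvals.items()
        ]

    def test_identical_inputs_return_topk(self):
        stats = self._ranked_stats({"a": 0.01, "b": 0.02, "c": 0.5})
        assert ds.select_dropout_genes(stats, stats, top_k=2) == ["a", "b"]

    def test_intersection_of_differing_topk(self):
        st_stats = self._ranked_stats({"a": 0.01, "b": 0.02, "c": 0.5})
        sc_stats = self._ranked_stats({"b": 0.01, "c": 0.02, "a": 0.5})
        assert ds.select_dropout_genes(st_stats, sc_stats, top_k=2) == ["b"]

    def test_empty_intersection_raises(self):
        st_stats = self._ranked_stats({"a": 0.01, "b": 0.5})
        sc_stats = self._ranked_stats({"c": 0.01, "d": 0.5})
        with pytest.raises(ValueError, match="top_k"):
            ds.select_dropout_genes(st_stats, sc_stats, top_k=1)

    def test_symmetric_up_to_ordering(self):
        st_stats = self._ranked_stats({"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.9})
        sc_stats = self._ranked_stats({"b": 0.01, "c": 0.015, "a": 0.2, "d": 0.9})
        fwd = ds.select_dropout_genes(st_stats, sc_stats, top_k=3)
        rev = ds.select_dropout_genes(sc_stats, st_stats, top_k=3)
        assert set(fwd) == set(rev)

    def test_recovers_inflated_genes_against_enumeration_oracle(self, rng):
        """Genes with 20x-inflated K must fill the top-10 of both datasets."""
        n_obs, K_M = 300, 1.0
        genes = []
        for i in range(100):
            E = float(rng.uniform(1.0, 4.0))
            K = K_M * 20 if i < 10 else K_M
            zeros = int(np.clip(round(n_obs * K / (E + K)), 1, n_obs - 1))
            genes.append(GeneDropoutStats(f"g{i:03d}", E=E, P=zeros / n_obs))
        fit = ds.fit_global_KM(genes, n_obs)
        ds.test_gene_significance(genes, fit, n_obs)
        picked = ds.select_dropout_genes(genes, genes, top_k=10)
        assert sorted(picked) == [f"g{i:03d}" for i in range(10)]
        # oracle: exact right-tail binomial p-values under the fitted K rank
        # the same 10 genes first
        oracle_p = {
            s.gene_id: binom.sf(round(s.P * n_obs) - 1, n_obs, fit.K_M / (s.E + fit.K_M))
            for s in genes
        }
        oracle_top = sorted(oracle_p, key=lambda g: oracle_p[g])[:10]
        assert sorted(oracle_top) == sorted(picked)
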