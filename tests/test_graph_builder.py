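import numpy as np
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from graphdeconv import graph_builder as gb
from graphdeconv.io_formats import ProportionMatrix, SpotCoordinates


def brute_force_mutual_knn(pseudo, real, k):
    """O(n^2) oracle: rank all pairwise distances and intersect."""
    d = cdist(pseudo, real)
    p_near = {p: set(np.argsort(d[p], kind="stable")[:k]) for p in range(len(pseudo))}
    r_near = {r: set(np.argsort(d[:, r], kind="stable")[:k]) for r in range(len(real))}
    return sorted(
        (p, r)
        for p in range(len(pseudo))
        for r in range(len(real))
        if r in p_near[p] and p in r_near[r]
    )


class TestMutualKnn:
    def test_large_k_gives_complete_bipartite(self, rng):
        p, r = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        edges = gb.mutual_knn_edges(p, r, k=10)
        assert len(edges) == 4 * 5

    def test_single_pair_always_linked(self, rng):
        edges = gb.mutual_knn_edges(rng.normal(size=(1, 2)), rng.normal(size=(1, 2)), k=1)
        assert edges == [(0, 0)]

    def test_matches_brute_force_oracle(self, rng):
        p, r = rng.uniform(size=(10, 4)), rng.uniform(size=(10, 4))
        assert gb.mutual_knn_edges(p, r, k=3) == brute_force_mutual_knn(p, r, 3)

    def test_monotone_in_k(self, rng):
        p, r = rng.uniform(size=(12, 3)), rng.uniform(size=(9, 3))
        for k in range(1, 8):
            assert set(gb.mutual_knn_edges(p, r, k)) <= set(
                gb.mutual_knn_edges(p, r, k + 1)
            )

    def test_mismatched_dims_rejected(self, rng):
        with pytest.raises(ValueError):
            gb.mutual_knn_edges(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)), k=1)


def brute_force_spatial(xy, h, tol=0.15):
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, 0.5], [0.5, -0.5]]) * h
    edges = set()
    for i in range(len(xy)):
        for off in offsets:
            target = xy[i] + off
            d = np.linalg.norm(xy - target, axis=1)
            j = int(np.argmin(d))
            if j != i and d[j] <= tol * h:
                edges.add((min(i, j), max(i, j)))
    return sorted(edges)


class TestSpatialEdges:
    def test_single_spot_has_no_edges(self):
        coords = SpotCoordinates(["s"], [0.0], [0.0], pitch_h=1.0)
        assert gb.spatial_edges(coords, h=1.0) == []

    def test_exact_diagonal_neighbors_link(self):
        coords = SpotCoordinates(["a", "b"], [0.0, 0.5], [0.0, 0.5], pitch_h=1.0)
        assert gb.spatial_edges(coords, h=1.0) == [(0, 1)]

    def test_staggered_two_rows_match_brute_force(self):
        h = 2.0
        xy = np.array(
            [[0, 0], [h, 0], [2 * h, 0], [h / 2, h / 2], [3 * h / 2, h / 2], [5 * h / 2, h / 2]],
            dtype=float,
        )
        coords = SpotCoordinates([f"s{i}" for i in range(6)], xy[:, 0], xy[:, 1])
        assert gb.spatial_edges(coords, h=h) == brute_force_spatial(xy, h)

    def test_non_lattice_layout_falls_back_to_four_nn(self, rng, caplog):
        xy = rng.uniform(0, 10, size=(20, 2))
        coords = SpotCoordinates([f"s{i}" for i in range(20)], xy[:, 0], xy[:, 1])
        with caplog.at_level("WARNING"):
            edges = gb.spatial_edges(coords, h=1.0)
        assert "falling back" in caplog.text
        # every node appears in some edge under the 4-NN fallback
        touched = {i for e in edges for i in e}
        assert touched == set(range(20))

    def test_nonpositive_pitch_rejected(self):
        coords = SpotCoordinates(["a", "b"], [0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            gb.spatial_edges(coords, h=0.0)

    def test_pitch_estimated_from_staggered_lattice(self):
        from graphdeconv.synthetic_data import staggered_lattice

        pts, ids = staggered_lattice(4, 4, h=100.0)
        coords = SpotCoordinates(ids, pts[:, 0], pts[:, 1])
        assert gb.estimate_pitch(coords) == pytest.approx(100.0, rel=1e-6)


class TestNormalizeAdjacency:
    def test_isolated_node_gets_unit_self_loop(self):
        A = sp.csr_matrix((1, 1))
        np.testing.assert_allclose(gb.normalize_adjacency(A).toarray(), [[1.0]])

    def test_two_node_edge_closed_form(self):
        A = sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
        np.testing.assert_allclose(
            gb.normalize_adjacency(A).toarray(), [[0.5, 0.5], [0.5, 0.5]]
        )

    def test_random_graph_matches_dense_closed_form(self, rng):
        n = 8
        upper = rng.integers(0, 2, size=(n, n))
        A_dense = np.triu(upper, 1)
        A_dense = A_dense + A_dense.T
        A_hat = A_dense + np.eye(n)
        d_inv_sqrt = np.diag(1 / np.sqrt(A_hat.sum(axis=1)))
        expected = d_inv_sqrt @ A_hat @ d_inv_sqrt
        got = gb.normalize_adjacency(sp.csr_matrix(A_dense)).toarray()
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_regular_graph_rows_sum_to_one(self):
        # 4-cycle: every node has degree 2
        A = sp.csr_matrix(
            np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], float)
        )
        rowsums = gb.normalize_adjacency(A).toarray().sum(axis=1)
        np.testing.assert_allclose(rowsums, 1.0, atol=1e-12)


def _labels(n, T=2):
    vals = np.zeros((n, T))
    vals[:, 0] = 1.0
    return ProportionMatrix([f"pseudo_{i}" for i in range(n)], [f"t{j}" for j in range(T)], vals)


class TestAssembleGraph:
    def test_small_graph_counts(self, rng):
        g = gb.assemble_graph(
            rng.normal(size=(2, 3)), rng.normal(size=(1, 3)),
            [(0, 0)], [], _labels(2), split_seed=0,
        )
        assert g.n_nodes == 3
        assert g.A.nnz == 2  # one symmetric pair
        assert g.A.diagonal().sum() == 0

    def test_empty_edges_give_identity_propagation(self, rng):
        g = gb.assemble_graph(
            rng.normal(size=(3, 2)), rng.normal(size=(2, 2)), [], [], _labels(3), 0
        )
        np.testing.assert_allclose(g.A_norm.toarray(), np.eye(5))

    def test_split_sizes_and_disjointness(self, rng):
        g = gb.assemble_graph(
            rng.normal(size=(10, 2)), rng.normal(size=(2, 2)), [], [], _labels(10), 7
        )
        parts = [set(g.pseudo_train), set(g.pseudo_val), set(g.pseudo_test)]
        assert [len(p) for p in parts] == [8, 1, 1]
        assert parts[0] | parts[1] | parts[2] == set(range(10))
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_out_of_range_edges_rejected(self, rng):
        with pytest.raises(ValueError):
            gb.assemble_graph(
                rng.normal(size=(2, 2)), rng.normal(size=(1, 2)),
                [(0, 5)], [], _labels(2), 0,
            )

    def test_edge_kinds_are_bipartite_by_construction(self, easy_result):
        g = easy_result.graph
        for p, r in easy_result.knn_edges:
            assert 0 <= p < g.n_pseudo and 0 <= r < g.n_real
        for i, j in easy_result.spatial_edges:
            assert 0 <= i < g.n_real and 0 <= j < g.n_real
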