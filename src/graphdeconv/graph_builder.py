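"""Graph assembly over pseudo- and real-ST spots.

Two edge kinds, both unweighted:

* transcriptional — mutual k-nearest-neighbor edges between pseudo and real
  spots in the embedded space (an edge exists only when each endpoint is
  within the other's k nearest from the opposite set);
* spatial — edges among real spots whose coordinates sit at the four
  diagonal lattice offsets (+/- h/2, +/- h/2) of one another, where h is the
  spot-to-spot horizontal pitch.

The node order is [pseudo | real].  Propagation uses the renormalized
adjacency A~ = D^{-1/2} (A + I) D^{-1/2}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_formats import ProportionMatrix, SpotCoordinates

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionGraph:
    """Features, adjacency and masks for the semi-supervised deconvolution."""

    X: np.ndarray  # N x g_a, rows ordered [pseudo | real]
    A: sp.csr_matrix  # binary symmetric, zero diagonal
    A_norm: sp.csr_matrix
    n_pseudo: int
    n_real: int
    labels: ProportionMatrix  # over pseudo nodes
    pseudo_train: np.ndarray
    pseudo_val: np.ndarray
    pseudo_test: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.n_pseudo + self.n_real

    @property
    def real_indices(self) -> np.ndarray:
        return np.arange(self.n_pseudo, self.n_nodes)


def mutual_knn_edges(
    pseudo_emb: np.ndarray,
    real_emb: np.ndarray,
    k: int = 100,
    metric: str = "euclidean",
) -> list[tuple[int, int]]:
    """Mutual k-NN edges between pseudo and real spots in embedded space.

    Edge (p, r) exists iff r is among the k nearest real spots to p AND p is
    among the k nearest pseudo spots to r.  Ties at the k-th rank are broken
    by node index (stable argsort), so the edge set is deterministic.
    """
    pseudo_emb = np.asarray(pseudo_emb, float)
    real_emb = np.asarray(real_emb, float)
    if pseudo_emb.shape[1] != real_emb.shape[1]:
        raise ValueError("embeddings must share dimensionality")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_p, n_r = len(pseudo_emb), len(real_emb)
    if k > max(n_p, n_r):
        logger.warning("k=%d exceeds both set sizes; clamping", k)
    k_r = min(k, n_r)  # neighbors of a pseudo spot among real spots
    k_p = min(k, n_p)

    nn_real = NearestNeighbors(n_neighbors=k_r, metric=metric).fit(real_emb)
    p_to_r = nn_real.kneighbors(pseudo_emb, return_distance=False)
    nn_pseudo = NearestNeighbors(n_neighbors=k_p, metric=metric).fit(pseudo_emb)
    r_to_p = nn_pseudo.kneighbors(real_emb, return_distance=False)

    r_neighbor_sets = [set(row) for row in r_to_p]
    edges = set()
    for p in range(n_p):
        for r in p_to_r[p]:
            if p in r_neighbor_sets[r]:
                edges.add((p, int(r)))
    return sorted(edges)


def estimate_pitch(coords: SpotCoordinates) -> float:
    """Modal nearest-neighbor distance times sqrt(2).

    On a staggered lattice the nearest neighbors sit diagonally at distance
    h/sqrt(2), so the pitch is that distance scaled back up.
    """
    xy = coords.xy
    if len(xy) < 2:
        raise ValueError("need at least 2 spots to estimate pitch")
    nn = NearestNeighbors(n_neighbors=2).fit(xy)
    d, _ = nn.kneighbors(xy)
    nnd = d[:, 1]
    # mode of rounded distances, robust to jitter
    vals, counts = np.unique(np.round(nnd, 6), return_counts=True)
    modal = float(vals[np.argmax(counts)])
    h = modal * np.sqrt(2.0)
    logger.info("estimated lattice pitch h=%.4g from modal NN distance", h)
    return h


def spatial_edges(
    coords: SpotCoordinates,
    h: float | None = None,
    tol: float = 0.15,
) -> list[tuple[int, int]]:
    """Link each real spot to the spots at its four diagonal lattice offsets.

    For a spot at (x, y) the four target positions are
    (x - h/2, y - h/2), (x - h/2, y + h/2), (x + h/2, y + h/2),
    (x + h/2, y - h/2); a spot within tol*h of a target is linked.  On
    layouts where the diagonal offsets match no spots (non-staggered grids,
    irregular sections) the builder falls back — with a logged notice — to
    linking each spot to its 4 nearest spatial neighbors, preserving the
    four-neighbor intent.  The edge set is symmetrized and deduplicated.
    """
    if h is None:
        h = coords.pitch_h if coords.pitch_h is not None else estimate_pitch(coords)
    if h <= 0:
        raise ValueError("pitch h must be positive")
    xy = coords.xy
    n = len(xy)
    if n < 2:
        return []

    nn = NearestNeighbors(n_neighbors=min(5, n)).fit(xy)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, 0.5], [0.5, -0.5]]) * h
    edges: set[tuple[int, int]] = set()
    matched = np.zeros(n, dtype=bool)
    for i in range(n):
        targets = xy[i] + offsets
        dist, idx = nn.kneighbors(targets)
        for d0, j0 in zip(dist[:, 0], idx[:, 0]):
            j = int(j0)
            if j != i and d0 <= tol * h:
                edges.add((min(i, j), max(i, j)))
                matched[i] = True

    if matched.mean() < 0.5:
        logger.warning(
            "spatial layout does not match the staggered-lattice offsets "
            "(%d/%d spots matched); falling back to 4 nearest neighbors",
            int(matched.sum()),
            n,
        )
        k = min(5, n)
        _, idx = nn.kneighbors(xy)
        edges = set()
        for i in range(n):
            for j in idx[i, 1:k]:
                edges.add((min(i, int(j)), max(i, int(j))))
    return sorted(edges)


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """A~ = D^{-1/2} (A + I) D^{-1/2} with D the degree matrix of A + I.

    Isolated nodes receive self-loop weight exactly 1.
    """
    A = sp.csr_matrix(A)
    A_hat = A + sp.identity(A.shape[0], format="csr")
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return sp.csr_matrix(D @ A_hat @ D)


def split_masks(
    n: int, seed: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded shuffle split of n indices into train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return (
        np.sort(order[:n_train]),
        np.sort(order[n_train : n_train + n_val]),
        np.sort(order[n_train + n_val :]),
    )


def assemble_graph(
    pseudo_emb: np.ndarray,
    real_emb: np.ndarray,
    knn_edges: list[tuple[int, int]],
    spatial_edge_list: list[tuple[int, int]],
    labels: ProportionMatrix,
    split_seed: int = 0,
) -> DeconvolutionGraph:
    """Stack features [pseudo | real], build binary A and A~, split pseudo nodes.

    knn edges are (pseudo_idx, real_idx) in set-local indexing; spatial edges
    are (real_idx, real_idx).  Pseudo nodes get a seeded 80/10/10
    train/val/test split; real nodes carry no labels.
    """
    n_p, n_r = len(pseudo_emb), len(real_emb)
    if labels.n_obs != n_p:
        raise ValueError("labels must cover exactly the pseudo nodes")
    X = np.vstack([pseudo_emb, real_emb])
    N = n_p + n_r

    rows, cols = [], []
    for p, r in knn_edges:
        if not (0 <= p < n_p and 0 <= r < n_r):
            raise ValueError(f"knn edge ({p},{r}) out of range")
        rows += [p, n_p + r]
        cols += [n_p + r, p]
    for i, j in spatial_edge_list:
        if not (0 <= i < n_r and 0 <= j < n_r) or i == j:
            raise ValueError(f"spatial edge ({i},{j}) out of range")
        rows += [n_p + i, n_p + j]
        cols += [n_p + j, n_p + i]
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(N, N)
    )
    A.data[:] = 1.0  # deduplicate parallel edges
    A = sp.csr_matrix(A)

    train, val, test = split_masks(n_p, split_seed)
    return DeconvolutionGraph(
        X=X,
        A=A,
        A_norm=normalize_adjacency(A),
        n_pseudo=n_p,
        n_real=n_r,
        labels=labels,
        pseudo_train=train,
        pseudo_val=val,
        pseudo_test=test,
    )


def export_edges_tsv(
    knn_edges: list[tuple[int, int]],
    spatial_edge_list: list[tuple[int, int]],
    path,
) -> None:
    """Edge list as TSV: src, dst, kind in {knn, spatial}."""
    with open(path, "w") as fh:
        fh.write("src\tdst\tkind\n")
        for p, r in knn_edges:
            fh.write(f"{p}\t{r}\tknn\n")
        for i, j in spatial_edge_list:
            fh.write(f"{i}\t{j}\tspatial\n")
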