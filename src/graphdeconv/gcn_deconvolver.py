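"""Semi-supervised graph convolutional deconvolution.

A three-layer graph convolutional network propagates node features through
the renormalized adjacency A~:

    H^{l+1} = ReLU(A~ H^l W^l)          (first two layers)
    C       = softmax(A~ H^2 W^2)        (output layer, row-wise)

Pseudo-spot nodes carry exact composition labels; training minimizes
soft-label cross-entropy -sum_t y_t log(c_t) over the labelled (training)
nodes, full-batch, with Adam and early stopping on a validation subset of
the pseudo nodes.  The softmax output rows sum to 1 and are read directly as
cell-type proportions; the rows at real-spot indices are the deconvolution
result.

Implemented on numpy/scipy sparse — the graphs here are small, and a
self-contained implementation keeps runs bit-reproducible per seed.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .embedding import _Adam, _glorot
from .graph_builder import DeconvolutionGraph
from .io_formats import ProportionMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-9  # inside the log of the cross-entropy


@dataclass
class GCNModel:
    """Three-layer GCN weights and the training history."""

    weights: list[np.ndarray]  # W0: g_a x d1, W1: d1 x d2, W2: d2 x T
    training_log: list[tuple[int, float, float]] = field(default_factory=list)
    best_epoch: int = -1
    trained: bool = False

    @property
    def n_types(self) -> int:
        return self.weights[-1].shape[1]


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(
    model: GCNModel, A_norm: sp.spmatrix, X: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass keeping pre-activations and propagated inputs for backprop."""
    pre, prop = [], []
    H = X
    for l, W in enumerate(model.weights):
        AH = A_norm @ H
        prop.append(AH)
        Z = AH @ W
        pre.append(Z)
        H = np.maximum(Z, 0.0) if l < len(model.weights) - 1 else Z
    return _softmax_rows(H), pre, prop


def gcn_forward(model: GCNModel, graph: DeconvolutionGraph) -> ProportionMatrix:
    """Predicted composition for every node; each row sums to 1."""
    if graph.X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"feature dim {graph.X.shape[1]} != model input {model.weights[0].shape[0]}"
        )
    out, _, _ = _forward_cached(model, graph.A_norm, graph.X)
    ids = [f"pseudo_{i}" for i in range(graph.n_pseudo)] + [
        f"real_{i}" for i in range(graph.n_real)
    ]
    return ProportionMatrix(ids, list(graph.labels.type_names), out)


def _cross_entropy(pred: np.ndarray, target: np.ndarray) -> float:
    return float(-np.mean(np.sum(target * np.log(pred + _EPS), axis=1)))


def init_gcn(
    feature_dim: int,
    n_types: int,
    hidden_dims: tuple[int, int] = (64, 32),
    seed: int = 0,
) -> GCNModel:
    """Seeded Glorot initialization of the three weight matrices."""
    rng = np.random.default_rng(seed)
    dims = [feature_dim, hidden_dims[0], hidden_dims[1], n_types]
    return GCNModel(weights=[_glorot(rng, a, b) for a, b in zip(dims, dims[1:])])


def train_gcn(
    graph: DeconvolutionGraph,
    lr: float = 0.005,
    max_epochs: int = 200,
    patience: int = 10,
    hidden_dims: tuple[int, int] = (64, 32),
    seed: int = 0,
) -> GCNModel:
    """Full-batch training with Adam, early-stopped on validation loss.

    The loss is soft-label cross-entropy over the pseudo training nodes;
    validation loss is monitored each epoch and training stops after
    ``patience`` epochs without improvement, restoring the best weights.
    """
    if len(graph.pseudo_train) < 1:
        raise ValueError("no labelled training nodes")
    Y = graph.labels.values
    T = Y.shape[1]
    model = init_gcn(graph.X.shape[1], T, hidden_dims, seed)
    opt = _Adam(model.weights, lr)

    train_idx = graph.pseudo_train
    val_idx = graph.pseudo_val
    best_val = np.inf
    best_weights = [w.copy() for w in model.weights]
    stall = 0

    for epoch in range(1, max_epochs + 1):
        out, pre, prop = _forward_cached(model, graph.A_norm, graph.X)

        # gradient of mean soft-label cross-entropy through the softmax
        dZ = np.zeros_like(out)
        dZ[train_idx] = (out[train_idx] - Y[train_idx]) / len(train_idx)
        grads: list[np.ndarray] = [None] * len(model.weights)
        for l in range(len(model.weights) - 1, -1, -1):
            grads[l] = prop[l].T @ dZ
            if l > 0:
                dH = graph.A_norm.T @ (dZ @ model.weights[l].T)
                dZ = dH * (pre[l - 1] > 0)
        if any(not np.all(np.isfinite(g)) for g in grads):
            raise FloatingPointError(f"non-finite gradient at epoch {epoch}")
        opt.step(model.weights, grads)

        out, _, _ = _forward_cached(model, graph.A_norm, graph.X)
        train_loss = _cross_entropy(out[train_idx], Y[train_idx])
        val_loss = (
            _cross_entropy(out[val_idx], Y[val_idx]) if len(val_idx) else train_loss
        )
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"NaN loss at epoch {epoch}")
        model.training_log.append((epoch, train_loss, val_loss))

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [w.copy() for w in model.weights]
            model.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                logger.info("early stop at epoch %d (best %d)", epoch, model.best_epoch)
                break

    model.weights = best_weights
    model.trained = True
    return model


def predict_real_proportions(
    model: GCNModel, graph: DeconvolutionGraph
) -> ProportionMatrix:
    """Rows of the forward pass restricted to the real-spot nodes."""
    if not model.trained:
        logger.warning("predicting with an untrained model: outputs near-uniform")
    full = gcn_forward(model, graph)
    idx = graph.real_indices
    return ProportionMatrix(
        [full.obs_ids[i] for i in idx],
        list(full.type_names),
        full.values[idx],
    )


def filter_low_proportions(
    c: ProportionMatrix, threshold: float = 0.05
) -> ProportionMatrix:
    """Zero out entries below ``threshold`` and renormalize each row.

    Motivated by spot capacity: with at most ~20 cells per spot, a type
    below 5% corresponds to an expected count under one cell.  If every
    entry of a row falls below the threshold, the row collapses to one-hot
    on its argmax (first index on ties).
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    values = c.values.copy()
    keep = values >= threshold
    for i in range(values.shape[0]):
        if not keep[i].any():
            one_hot = np.zeros_like(values[i])
            one_hot[int(np.argmax(values[i]))] = 1.0
            values[i] = one_hot
        else:
            values[i] = np.where(keep[i], values[i], 0.0)
            values[i] /= values[i].sum()
    return ProportionMatrix(list(c.obs_ids), list(c.type_names), values)


def export_training_log_tsv(model: GCNModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\n")
        for epoch, tr, va in model.training_log:
            fh.write(f"{epoch}\t{tr:.10g}\t{va:.10g}\n")
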