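"""Autoencoder embedding of spot expression profiles.

A three-layer autoencoder (input -> hidden bottleneck -> output) is trained
to reconstruct the stacked real + pseudo spot matrix under mean-squared
error; the hidden activations serve as the low-dimensional node features for
graph construction.  Implemented directly on numpy with Adam — the matrices
involved are small enough that a deep-learning framework buys nothing here,
and a self-contained implementation keeps training bit-reproducible per seed.

An SVD projection onto the top singular directions is provided as the linear
ablation counterpart; both paths emit identically shaped features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np


@dataclass
class EmbeddingModel:
    """Trained encoder/decoder weights plus the per-epoch loss log."""

    W_enc: np.ndarray  # input_dim x hidden_dim
    b_enc: np.ndarray
    W_dec: np.ndarray  # hidden_dim x input_dim
    b_dec: np.ndarray
    activation: Literal["relu", "linear"] = "relu"
    loss_log: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.W_enc.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W_enc.shape[1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    """Minimal Adam optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_autoencoder(
    x: np.ndarray,
    hidden_dim: int = 200,
    batch_size: int = 300,
    epochs: int = 5,
    seed: int = 0,
    lr: float = 1e-3,
    activation: Literal["relu", "linear"] = "relu",
) -> EmbeddingModel:
    """Train the bottleneck autoencoder on the stacked spot matrix.

    Mini-batched, with a deterministic per-seed shuffle each epoch.  The
    logged loss per epoch is the full-data reconstruction MSE after that
    epoch's updates.  ``epochs=0`` returns the untrained initialization with
    an empty log.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("NaN or Inf in autoencoder input")
    n, d = x.shape
    if hidden_dim >= d:
        import logging

        logging.getLogger(__name__).warning(
            "hidden_dim (%d) >= input_dim (%d): embedding is not compressive",
            hidden_dim,
            d,
        )

    rng = np.random.default_rng(seed)
    model = EmbeddingModel(
        W_enc=_glorot(rng, d, hidden_dim),
        b_enc=np.zeros(hidden_dim),
        W_dec=_glorot(rng, hidden_dim, d),
        b_dec=np.zeros(d),
        activation=activation,
    )
    params = [model.W_enc, model.b_enc, model.W_dec, model.b_dec]
    opt = _Adam(params, lr)

    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = x[order[start : start + batch_size]]
            h_pre = xb @ model.W_enc + model.b_enc
            h = np.maximum(h_pre, 0.0) if activation == "relu" else h_pre
            recon = h @ model.W_dec + model.b_dec
            # d(MSE)/d(recon), MSE averaged over all entries of the batch
            d_recon = 2.0 * (recon - xb) / xb.size
            g_Wd = h.T @ d_recon
            g_bd = d_recon.sum(axis=0)
            d_h = d_recon @ model.W_dec.T
            if activation == "relu":
                d_h = d_h * (h_pre > 0)
            g_We = xb.T @ d_h
            g_be = d_h.sum(axis=0)
            opt.step(params, [g_We, g_be, g_Wd, g_bd])
        model.loss_log.append(float(np.mean((x - _reconstruct(model, x)) ** 2)))
    return model


def _reconstruct(model: EmbeddingModel, x: np.ndarray) -> np.ndarray:
    return embed(model, x) @ model.W_dec + model.b_dec


def embed(model: EmbeddingModel, m: np.ndarray) -> np.ndarray:
    """Encode rows into the hidden space; output has ``hidden_dim`` columns."""
    m = np.asarray(m, dtype=float)
    if m.shape[1] != model.input_dim:
        raise ValueError(
            f"input has {m.shape[1]} columns, model expects {model.input_dim}"
        )
    h = m @ model.W_enc + model.b_enc
    if model.activation == "relu":
        h = np.maximum(h, 0.0)
    return h


def svd_embed(x: np.ndarray, n_components: int = 200) -> np.ndarray:
    """Project rows onto the top singular directions (linear ablation path)."""
    x = np.asarray(x, dtype=float)
    k = min(n_components, min(x.shape))
    # deterministic full SVD; matrices here are modest
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    out = x @ vt[:k].T
    if k < n_components:
        out = np.pad(out, ((0, 0), (0, n_components - k)))
    return out
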