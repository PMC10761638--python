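"""Learned attention fusion of per-sequence feature vectors.

For a lesion with per-sequence standardized vectors ``{f_1, ..., f_K}`` the
fused representation is the convex combination

    u_k = tanh(W f_k + b)
    w_k = exp(u_k^T u) / sum_j exp(u_j^T u)
    f   = sum_k w_k f_k

with the projection ``W`` (a x d), bias ``b`` (a) and feature-level context
vector ``u`` (a) shared across lesions and learned jointly with the graph
classifier.  The module provides the forward pass (vectorized over lesions)
and a hand-derived backward pass used by the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AttentionParams", "init_attention", "fuse", "attention_weights"]


@dataclass
class AttentionParams:
    W: np.ndarray  # (a, d)
    b: np.ndarray  # (a,)
    u: np.ndarray  # (a,)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        a, d = self.W.shape
        if self.b.shape != (a,) or self.u.shape != (a,):
            raise ValueError("inconsistent attention parameter shapes")
        if not all(np.all(np.isfinite(p)) for p in (self.W, self.b, self.u)):
            raise ValueError("attention parameters must be finite")

    @property
    def width(self) -> int:
        return self.W.shape[0]

    @property
    def dim(self) -> int:
        return self.W.shape[1]


def init_attention(d: int, a: int = 64, seed: int = 0,
                   scale: float = 0.05) -> AttentionParams:
    """Uniform(-scale, scale) init for W and u; zero bias. Seed-reproducible."""
    if d < 1 or a < 1:
        raise ValueError("d and a must be >= 1")
    rng = np.random.default_rng(seed)
    return AttentionParams(
        W=rng.uniform(-scale, scale, size=(a, d)),
        b=np.zeros(a),
        u=rng.uniform(-scale, scale, size=a),
    )


def _as_batch(bundle: np.ndarray) -> tuple[np.ndarray, bool]:
    F = np.asarray(bundle, dtype=float)
    if F.ndim == 2:
        return F[None], True
    if F.ndim != 3:
        raise ValueError("bundle must be (K, d) or (n, K, d)")
    return F, False


def _forward(F: np.ndarray, params: AttentionParams):
    if F.shape[-1] != params.dim:
        raise ValueError(
            f"bundle dimension {F.shape[-1]} != attention dimension {params.dim}")
    U = np.tanh(F @ params.W.T + params.b)          # (n, K, a)
    s = U @ params.u                                 # (n, K)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    w = e / e.sum(axis=1, keepdims=True)             # (n, K)
    fused = np.einsum("nk,nkd->nd", w, F)
    return fused, w, U


def fuse(bundle: np.ndarray, params: AttentionParams):
    """Fused vector(s) and attention weight(s) for one lesion or a batch.

    ``bundle`` is ``(K, d)`` for one lesion or ``(n, K, d)`` for a batch.
    Weights are strictly positive and sum to 1 per lesion, so the fused
    vector lies in the convex hull of the sequence vectors.
    """
    F, single = _as_batch(bundle)
    fused, w, _ = _forward(F, params)
    if single:
        return fused[0], w[0]
    return fused, w


def attention_weights(bundle: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Only the softmax modality weights of :func:`fuse`."""
    return fuse(bundle, params)[1]


# -- training support --------------------------------------------------------


def forward_cached(F: np.ndarray, params: AttentionParams):
    """Forward pass returning the cache needed by :func:`backward`."""
    fused, w, U = _forward(F, params)
    return fused, {"F": F, "w": w, "U": U, "params": params}


def backward(grad_fused: np.ndarray, cache: dict):
    """Gradients of the loss w.r.t. W, b, u given d(loss)/d(fused)."""
    F, w, U = cache["F"], cache["w"], cache["U"]
    params: AttentionParams = cache["params"]
    dw = np.einsum("nd,nkd->nk", grad_fused, F)
    ds = w * (dw - np.einsum("nk,nk->n", dw, w)[:, None])   # softmax backward
    dU = ds[:, :, None] * params.u[None, None, :]
    du = np.einsum("nk,nka->a", ds, U)
    dZ = dU * (1.0 - U ** 2)                                # tanh backward
    dW = np.einsum("nka,nkd->ad", dZ, F)
    db = dZ.sum(axis=(0, 1))
    return dW, db, du
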