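"""Lesion similarity graph and GraphSAGE node classifier.

The lesion graph is a kNN graph under cosine similarity ("similar score"),
symmetrized by union, with the similarity as edge weight.  GraphSAGE layers
update each node as

    h' = relu(W_self h + W_neigh mean_w(neighbours) + b)

where ``mean_w`` is the edge-weight-weighted mean of neighbour features (the
zero vector for an isolated node), followed by a linear softmax head over the
three mutation classes.  Forward passes are dense matrix products — cohorts
here are a few hundred lesions, so full-batch is the natural regime.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "similar_score", "cosine_matrix", "build_graph", "attach_nodes",
    "LesionGraph", "SageParams", "init_sage", "sage_forward",
]


def similar_score(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity; 0 when either vector has zero norm."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal dimension")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities between rows of A and rows of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    return (A / na[:, None]) @ (B / nb[:, None]).T


@dataclass
class LesionGraph:
    """kNN lesion graph with node features and a row-normalized aggregator."""

    features: np.ndarray          # (n, d)
    adjacency: np.ndarray         # (n, n) symmetric, zero diagonal
    k_neighbors: int

    def __post_init__(self):
        n = self.features.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def aggregator(self) -> np.ndarray:
        """Weighted-mean matrix, normalized by total absolute edge weight
        (zero rows for isolated nodes; robust to negative-similarity edges)."""
        rowsum = np.abs(self.adjacency).sum(axis=1, keepdims=True)
        safe = np.where(rowsum == 0, 1.0, rowsum)
        return self.adjacency / safe


def _knn_rows(S: np.ndarray, k: int) -> np.ndarray:
    """Boolean (n, m) matrix selecting each row's k largest entries.

    Ties are broken toward the lower column index for determinism.
    """
    n, m = S.shape
    sel = np.zeros((n, m), dtype=bool)
    cols = np.arange(m)
    for i in range(n):
        order = np.lexsort((cols, -S[i]))
        sel[i, order[:k]] = True
    return sel


def build_graph(vectors: np.ndarray, k_neighbors: int = 10) -> LesionGraph:
    """kNN graph over fused lesion vectors, symmetrized by union.

    Each node is linked to its ``k_neighbors`` most similar other nodes;
    edge weight is the cosine similarity.  ``k_neighbors`` is truncated (with
    a warning) when it reaches the node count.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one feature vector")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    n = X.shape[0]
    if k_neighbors >= n:
        if n > 1:
            logger.warning("k_neighbors=%d >= %d nodes; truncating to %d",
                           k_neighbors, n, n - 1)
        k_neighbors = max(n - 1, 0)
    S = cosine_matrix(X, X)
    np.fill_diagonal(S, -np.inf)
    A = np.zeros((n, n))
    if k_neighbors > 0:
        sel = _knn_rows(S, k_neighbors)
        sel = sel | sel.T  # union symmetrization
        A[sel] = S[sel]
    return LesionGraph(features=X, adjacency=A, k_neighbors=k_neighbors)


def attach_nodes(graph: LesionGraph, vectors: np.ndarray,
                 k_neighbors: int | None = None) -> np.ndarray:
    """Inductive attachment: aggregation weights of new nodes over the graph.

    Each new node is linked to its k most similar *training* nodes only (no
    edges among new nodes), mirroring GraphSAGE's inductive use.  Returns a
    row-stochastic ``(n_new, n_train)`` aggregator.
    """
    X = np.asarray(vectors, dtype=float)
    k = graph.k_neighbors if k_neighbors is None else k_neighbors
    k = min(k, graph.n_nodes)
    S = cosine_matrix(X, graph.features)
    sel = _knn_rows(S, k)
    W = np.where(sel, S, 0.0)
    rowsum = np.abs(W).sum(axis=1, keepdims=True)
    safe = np.where(rowsum == 0, 1.0, rowsum)
    return W / safe


# ---------------------------------------------------------------------------
# GraphSAGE parameters and forward/backward


@dataclass
class SageParams:
    """Per-layer self/neighbour weights plus the 3-class softmax head."""

    layers: list               # each: {"W_self", "W_neigh", "b"}
    head_W: np.ndarray         # (n_classes, hidden)
    head_b: np.ndarray         # (n_classes,)
    dropout: float = 0.2

    @property
    def input_dim(self) -> int:
        return self.layers[0]["W_self"].shape[1]

    @property
    def n_classes(self) -> int:
        return self.head_W.shape[0]

    def flat(self):
        out = []
        for lay in self.layers:
            out += [lay["W_self"], lay["W_neigh"], lay["b"]]
        out += [self.head_W, self.head_b]
        return out


def init_sage(d_in: int, n_classes: int = 3, hidden: int = 64,
              n_layers: int = 2, dropout: float = 0.2,
              seed: int = 0) -> SageParams:
    """Glorot-uniform initialization of a GraphSAGE stack."""
    rng = np.random.default_rng(seed)

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)

    layers = []
    din = d_in
    for _ in range(n_layers):
        layers.append({
            "W_self": glorot((hidden, din)),
            "W_neigh": glorot((hidden, din)),
            "b": np.zeros(hidden),
        })
        din = hidden
    return SageParams(layers=layers, head_W=glorot((n_classes, din)),
                      head_b=np.zeros(n_classes), dropout=dropout)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sage_forward(graph: LesionGraph, params: SageParams,
                 rng: np.random.Generator | None = None,
                 training: bool = False):
    """Per-node class probabilities (rows sum to 1).

    Dropout is active only when ``training`` is True and an ``rng`` is given.
    """
    probs, _ = sage_forward_cached(graph.features, graph.aggregator, params,
                                   rng=rng, training=training)
    return probs


def sage_forward_cached(X: np.ndarray, P: np.ndarray, params: SageParams,
                        rng=None, training: bool = False):
    """Forward pass keeping intermediates for :func:`sage_backward`."""
    if X.shape[1] != params.input_dim:
        raise ValueError(
            f"feature width {X.shape[1]} != network input {params.input_dim}")
    h = X
    cache = {"inputs": [], "aggs": [], "zs": [], "masks": [], "P": P}
    for lay in params.layers:
        agg = P @ h
        z = h @ lay["W_self"].T + agg @ lay["W_neigh"].T + lay["b"]
        a = np.maximum(z, 0.0)
        if training and rng is not None and params.dropout > 0:
            mask = (rng.random(a.shape) >= params.dropout) / (1.0 - params.dropout)
            a = a * mask
        else:
            mask = None
        cache["inputs"].append(h)
        cache["aggs"].append(agg)
        cache["zs"].append(z)
        cache["masks"].append(mask)
        h = a
    logits = h @ params.head_W.T + params.head_b
    cache["h_last"] = h
    probs = _softmax(logits)
    return probs, cache


def sage_backward(dlogits: np.ndarray, params: SageParams, cache: dict):
    """Gradients w.r.t. all SAGE parameters and the input features."""
    P = cache["P"]
    grads = {"layers": [], "head_W": dlogits.T @ cache["h_last"],
             "head_b": dlogits.sum(axis=0)}
    dh = dlogits @ params.head_W
    for li in range(len(params.layers) - 1, -1, -1):
        lay = params.layers[li]
        z = cache["zs"][li]
        mask = cache["masks"][li]
        if mask is not None:
            dh = dh * mask
        dz = dh * (z > 0)
        h_in = cache["inputs"][li]
        agg = cache["aggs"][li]
        g = {"W_self": dz.T @ h_in, "W_neigh": dz.T @ agg, "b": dz.sum(axis=0)}
        grads["layers"].insert(0, g)
        dh = dz @ lay["W_self"] + P.T @ (dz @ lay["W_neigh"])
    grads["X"] = dh
    return grads
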