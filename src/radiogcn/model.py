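"""Joint attention-fusion + GraphSAGE lesion classifier.

:class:`RadioGCNClassifier` is a scikit-learn style estimator.  ``fit`` takes
the horizontally concatenated per-sequence feature matrix ``X`` of shape
``(n_lesions, K * d)`` (sequence blocks in registry order) plus lesion labels
and patient ids, and jointly optimizes the attention parameters and the
GraphSAGE weights by class-weighted cross-entropy with Adam, selecting the
best epoch by validation macro one-vs-rest AUC.  Prediction is inductive:
test lesions attach to their most similar training lesions and never to each
other.

The ablation variants of the surrounding study map onto two switches:
``use_standardization`` (the L2+MinMax stage) and ``use_attention`` (without
it the K sequence blocks are simply concatenated as node features).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from . import attention as att
from . import graph as gr
from .standardization import ScalerState, apply_minmax, fit_minmax_columns, l2_normalize_rows

__all__ = ["RadioGCNClassifier", "ModelBundle", "train_model", "predict_lesions"]


def _macro_ovr_auc(y_idx: np.ndarray, probs: np.ndarray) -> float:
    aucs = []
    for c in range(probs.shape[1]):
        pos = y_idx == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, probs[:, c]))
    return float(np.mean(aucs)) if aucs else 0.5


class _Adam:
    def __init__(self, arrays, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RadioGCNClassifier(BaseEstimator, ClassifierMixin):
    """Attention-fused multisequence radiomics GraphSAGE classifier.

    Parameters
    ----------
    n_sequences
        Number K of MRI sequences stacked in ``X`` (columns = K blocks of
        equal width).
    use_standardization, use_attention
        Toggle the L2+MinMax stage and the attention fusion stage (ablation
        switches).  Without attention the sequence blocks are concatenated.
    attention_width
        Width ``a`` of the attention projection.
    k_neighbors
        kNN parameter of the lesion similarity graph.
    hidden, n_layers, dropout, lr, max_epochs, patience
        GraphSAGE architecture and Adam optimization settings; training stops
        after ``patience`` epochs without validation macro-AUC improvement.
    val_fraction
        Patient fraction split off for epoch selection when no explicit
        validation set is passed to ``fit``.
    seed
        Seed for initialization, dropout and the internal validation split.
    """

    def __init__(self, n_sequences: int = 4, use_standardization: bool = True,
                 use_attention: bool = True, attention_width: int = 64,
                 k_neighbors: int = 10, hidden: int = 64, n_layers: int = 2,
                 dropout: float = 0.2, lr: float = 1e-3, max_epochs: int = 300,
                 patience: int = 30, val_fraction: float = 0.2, seed: int = 0):
        self.n_sequences = n_sequences
        self.use_standardization = use_standardization
        self.use_attention = use_attention
        self.attention_width = attention_width
        self.k_neighbors = k_neighbors
        self.hidden = hidden
        self.n_layers = n_layers
        self.dropout = dropout
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # -- internal helpers ---------------------------------------------------

    def _split_blocks(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p % self.n_sequences:
            raise ValueError(f"{p} columns not divisible by K={self.n_sequences}")
        d = p // self.n_sequences
        return X.reshape(n, self.n_sequences, d)

    def _standardize(self, B: np.ndarray, fit: bool) -> np.ndarray:
        if not self.use_standardization:
            return B
        out = np.empty_like(B)
        if fit:
            self.scalers_ = []
        for k in range(self.n_sequences):
            Xl2 = l2_normalize_rows(B[:, k, :])
            if fit:
                self.scalers_.append(fit_minmax_columns(Xl2))
            out[:, k, :] = apply_minmax(Xl2, self.scalers_[k])
        return out

    def _node_features(self, B: np.ndarray, params=None):
        """Fused (or concatenated) node features; params defaults to fitted.

        Features are centered by the column means of the initial training
        node features (``center_``, fixed at initialization) — a pure
        conditioning step that removes the common-mode activation a
        nonnegative input range would otherwise induce.
        """
        if self.use_attention:
            p = params if params is not None else self.attention_params_
            fused, _ = att.fuse(B, p)
        else:
            fused = B.reshape(B.shape[0], -1)
        if getattr(self, "center_", None) is not None:
            fused = fused - self.center_
        return fused

    def _val_split(self, y_idx, patient_ids, rng):
        pids = np.asarray(patient_ids)
        val_pids = []
        for c in np.unique(y_idx):
            cpids = np.unique(pids[y_idx == c])
            cpids = cpids[rng.permutation(len(cpids))]
            n_val = max(1, int(round(self.val_fraction * len(cpids))))
            if n_val >= len(cpids):
                raise ValueError("not enough patients per class for a validation split")
            val_pids.extend(cpids[:n_val])
        val_mask = np.isin(pids, val_pids)
        return ~val_mask, val_mask

    def _inductive_probs(self, B_new, layer_inputs):
        """Forward pass for nodes attached inductively to the training graph.

        Attachment similarity uses the same standardized-concatenation basis
        the training adjacency was initialized from, so a lesion's
        neighbourhood is independent of the evolving attention state; node
        features are the centered fused vectors.
        """
        sage = layer_inputs["sage"]
        X_new = self._node_features(B_new, layer_inputs["attention"])
        sims = gr.cosine_matrix(B_new.reshape(len(B_new), -1),
                                layer_inputs["basis"])
        k = min(self.k_neighbors, sims.shape[1])
        sel = gr._knn_rows(sims, k)
        W = np.where(sel, sims, 0.0)
        rowsum = np.abs(W).sum(axis=1, keepdims=True)
        P_new = W / np.where(rowsum == 0, 1.0, rowsum)

        h = X_new
        for li, lay in enumerate(sage.layers):
            agg = P_new @ layer_inputs["hidden"][li]
            z = h @ lay["W_self"].T + agg @ lay["W_neigh"].T + lay["b"]
            h = np.maximum(z, 0.0)
        logits = h @ sage.head_W.T + sage.head_b
        return gr._softmax(logits)

    def _train_layer_inputs(self, B_train, attention_params, sage_params):
        """Node features and per-layer inputs of the training graph."""
        X = self._node_features(B_train, attention_params)
        _, cache = gr.sage_forward_cached(X, self.graph_.aggregator,
                                          sage_params, training=False)
        return {"X": X, "basis": B_train.reshape(len(B_train), -1),
                "hidden": cache["inputs"], "sage": sage_params,
                "attention": attention_params}

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, patient_ids=None, X_val=None, y_val=None):
        B_all = self._split_blocks(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.seed)

        if X_val is not None:
            B_tr, yi_tr = B_all, y_idx
            B_va = self._split_blocks(X_val)
            yi_va = np.searchsorted(self.classes_, np.asarray(y_val))
        else:
            if patient_ids is None:
                patient_ids = np.arange(len(y))  # every lesion its own patient
            tr_mask, va_mask = self._val_split(y_idx, patient_ids, rng)
            B_tr, yi_tr = B_all[tr_mask], y_idx[tr_mask]
            B_va, yi_va = B_all[va_mask], y_idx[va_mask]

        if len(np.unique(yi_tr)) < len(self.classes_):
            raise ValueError("a class is absent from the training split")

        B_tr = self._standardize(B_tr, fit=True)
        B_va = self._standardize(B_va, fit=False)

        n, K, d = B_tr.shape
        n_classes = len(self.classes_)
        if self.use_attention:
            att_params = att.init_attention(d, self.attention_width,
                                            seed=self.seed)
            d_in = d
        else:
            att_params = None
            d_in = K * d
        sage_params = gr.init_sage(d_in, n_classes, self.hidden,
                                   self.n_layers, self.dropout,
                                   seed=self.seed + 1)

        # adjacency initialized once from the similarity of the standardized
        # concatenation and held fixed during optimization; node features
        # (the fused vectors) evolve with the attention parameters
        self.graph_ = gr.build_graph(B_tr.reshape(n, -1), self.k_neighbors)
        self.center_ = None
        X_init = self._node_features(B_tr, att_params)
        self.center_ = X_init.mean(axis=0)
        P = self.graph_.aggregator

        counts = np.bincount(yi_tr, minlength=n_classes)
        cw = counts.sum() / (n_classes * np.maximum(counts, 1))
        w_i = cw[yi_tr]
        onehot = np.eye(n_classes)[yi_tr]

        arrays = ([att_params.W, att_params.b, att_params.u]
                  if self.use_attention else []) + sage_params.flat()
        opt = _Adam(arrays, lr=self.lr)
        drop_rng = np.random.default_rng(self.seed + 2)

        best = {"auc": -np.inf, "epoch": -1, "arrays": None}
        history = []
        since_best = 0
        for epoch in range(self.max_epochs):
            if self.use_attention:
                fused, acache = att.forward_cached(B_tr, att_params)
            else:
                fused = B_tr.reshape(n, -1)
            fused = fused - self.center_  # constant shift, gradient-transparent
            probs, scache = gr.sage_forward_cached(fused, P, sage_params,
                                                   rng=drop_rng, training=True)
            loss = float(-(w_i * np.log(probs[np.arange(n), yi_tr] + 1e-12)).sum()
                         / w_i.sum())
            dlogits = (probs - onehot) * w_i[:, None] / w_i.sum()
            grads = gr.sage_backward(dlogits, sage_params, scache)
            gl = []
            if self.use_attention:
                dW, db, du = att.backward(grads["X"].reshape(n, -1), acache)
                gl += [dW, db, du]
            for g in grads["layers"]:
                gl += [g["W_self"], g["W_neigh"], g["b"]]
            gl += [grads["head_W"], grads["head_b"]]
            opt.step(arrays, gl)

            # epoch selection on the validation split (no dropout)
            layer_inputs = self._train_layer_inputs(B_tr, att_params, sage_params)
            val_probs = self._inductive_probs(B_va, layer_inputs)
            val_auc = _macro_ovr_auc(yi_va, val_probs)
            history.append({"epoch": epoch, "loss": loss, "val_auc": val_auc})
            if val_auc > best["auc"] + 1e-12:
                best = {"auc": val_auc, "epoch": epoch,
                        "arrays": [a.copy() for a in arrays]}
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break

        # restore the best-epoch parameters
        if best["arrays"] is not None:
            for a, ba in zip(arrays, best["arrays"]):
                a[...] = ba
        self.attention_params_ = att_params
        self.sage_params_ = sage_params
        self.best_epoch_ = best["epoch"]
        self.best_val_auc_ = best["auc"]
        self.history_ = history
        self._B_train = B_tr
        self._layer_inputs = self._train_layer_inputs(B_tr, att_params,
                                                      sage_params)
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "sage_params_")
        B = self._standardize(self._split_blocks(X), fit=False)
        return self._inductive_probs(B, self._layer_inputs)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]  # ties -> lower index

    def attention_weights(self, X):
        """Per-lesion modality attention weights (requires use_attention)."""
        check_is_fitted(self, "attention_params_")
        if not self.use_attention:
            raise ValueError("model was fitted without attention")
        B = self._standardize(self._split_blocks(X), fit=False)
        return att.attention_weights(B, self.attention_params_)


# ---------------------------------------------------------------------------
# cross-validated training over patient folds


@dataclass
class ModelBundle:
    """A fitted fold model plus everything needed to reapply it."""

    model: RadioGCNClassifier
    fold: int
    registry_hash: str | None = None

    def save(self, directory: str | Path):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        m = self.model
        arrays = {}
        if m.use_attention:
            arrays.update(att_W=m.attention_params_.W,
                          att_b=m.attention_params_.b,
                          att_u=m.attention_params_.u)
        for i, lay in enumerate(m.sage_params_.layers):
            arrays[f"sage{i}_W_self"] = lay["W_self"]
            arrays[f"sage{i}_W_neigh"] = lay["W_neigh"]
            arrays[f"sage{i}_b"] = lay["b"]
        arrays["head_W"] = m.sage_params_.head_W
        arrays["head_b"] = m.sage_params_.head_b
        if m.use_standardization:
            for k, st in enumerate(m.scalers_):
                arrays[f"scaler{k}_min"] = st.minimum
                arrays[f"scaler{k}_range"] = st.range_
        arrays["train_blocks"] = m._B_train
        arrays["graph_adj"] = m.graph_.adjacency
        np.savez(directory / "arrays.npz", **arrays)
        meta = {"fold": self.fold, "registry_hash": self.registry_hash,
                "classes": list(map(str, m.classes_)),
                "best_epoch": m.best_epoch_,
                "params": m.get_params()}
        (directory / "model.json").write_text(json.dumps(meta, indent=2))


def train_model(matrices: dict[str, np.ndarray], labels, patient_ids,
                fold_assignment, hyperparams: dict | None = None,
                seed: int = 0, registry_hash: str | None = None
                ) -> list[ModelBundle]:
    """K-fold cross-validated training over patient-disjoint folds.

    ``matrices`` maps sequence name to an ``(n_lesions, d)`` matrix;
    ``fold_assignment`` is the DataFrame from
    :func:`radiogcn.synthetic.make_patient_folds`.  Each fold serves once as
    the validation set for epoch selection.
    """
    hyperparams = dict(hyperparams or {})
    seqs = list(matrices)
    X = np.hstack([np.asarray(matrices[s], dtype=float) for s in seqs])
    labels = np.asarray(labels)
    pids = np.asarray(patient_ids)
    fold_of = dict(zip(fold_assignment["patient_id"], fold_assignment["fold"]))
    lesion_fold = np.array([fold_of[p] for p in pids])

    bundles = []
    for fold in sorted(set(lesion_fold)):
        va = lesion_fold == fold
        tr = ~va
        if len(np.unique(labels[tr])) < len(np.unique(labels)):
            raise ValueError(f"a class is absent from fold {fold}'s training split")
        clf = RadioGCNClassifier(n_sequences=len(seqs),
                                 seed=seed + int(fold), **hyperparams)
        clf.fit(X[tr], labels[tr], X_val=X[va], y_val=labels[va])
        bundles.append(ModelBundle(model=clf, fold=int(fold),
                                   registry_hash=registry_hash))
    return bundles


def predict_lesions(bundle: ModelBundle, matrices: dict[str, np.ndarray]
                    ) -> np.ndarray:
    """Lesion-wise class probability vectors from a fold model."""
    X = np.hstack([np.asarray(matrices[s], dtype=float) for s in matrices])
    return bundle.model.predict_proba(X)
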