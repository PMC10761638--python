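"""Dual feature standardization: row-wise L2 norm, then column-wise MinMax.

This stage replaces classical feature selection.  Each lesion's feature
vector is first scaled to unit L2 norm (so the sum of squared features per
sample is 1), then every feature column is affinely mapped so the *training*
values span [0, 1].  Column statistics are learned from training rows only
and reused unchanged on test rows, which are deliberately not clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScalerState",
    "l2_normalize_rows",
    "fit_minmax_columns",
    "apply_minmax",
    "standardize",
    "FeatureStandardizer",
]


@dataclass
class ScalerState:
    """Per-column minimum and range learned from training rows."""

    minimum: np.ndarray
    range_: np.ndarray
    registry_hash: str | None = None

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.range_ = np.asarray(self.range_, dtype=float)
        if self.minimum.shape != self.range_.shape:
            raise ValueError("minimum and range shapes differ")
        if np.any(self.range_ < 0):
            raise ValueError("ranges must be >= 0")

    def to_json(self) -> str:
        return json.dumps({
            "minimum": self.minimum.tolist(),
            "range": self.range_.tolist(),
            "registry_hash": self.registry_hash,
        })

    @classmethod
    def from_json(cls, s: str) -> "ScalerState":
        d = json.loads(s)
        return cls(minimum=np.array(d["minimum"]), range_=np.array(d["range"]),
                   registry_hash=d.get("registry_hash"))


def l2_normalize_rows(X: np.ndarray) -> np.ndarray:
    """Scale each row to unit L2 norm; all-zero rows are left unchanged."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=-1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return X / safe


def fit_minmax_columns(X: np.ndarray, registry_hash: str | None = None) -> ScalerState:
    """Learn per-column min and range (max - min) from training rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    mn = X.min(axis=0)
    return ScalerState(minimum=mn, range_=X.max(axis=0) - mn,
                       registry_hash=registry_hash)


def apply_minmax(X: np.ndarray, state: ScalerState,
                 registry_hash: str | None = None) -> np.ndarray:
    """(x - min) / range per column; zero-range columns map to 0.

    Test rows may land outside [0, 1]; they are not clipped.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != state.minimum.shape[0]:
        raise ValueError("column count does not match scaler state")
    if (registry_hash is not None and state.registry_hash is not None
            and registry_hash != state.registry_hash):
        raise ValueError("feature registry hash mismatch")
    rng = np.where(state.range_ == 0, 1.0, state.range_)
    out = (X - state.minimum) / rng
    out[..., state.range_ == 0] = 0.0
    return out


def standardize(matrices: dict[str, np.ndarray],
                states: dict[str, ScalerState] | None = None
                ) -> tuple[dict[str, np.ndarray], dict[str, ScalerState]]:
    """Standardize per-sequence matrices: L2 rows first, then column MinMax.

    With ``states=None`` the MinMax statistics are fitted on the (L2
    normalized) input matrices; otherwise the provided training states are
    applied.  Sequences are processed independently.
    """
    out, used = {}, {}
    for seq, X in matrices.items():
        Xl2 = l2_normalize_rows(X)
        st = fit_minmax_columns(Xl2) if states is None else states[seq]
        out[seq] = apply_minmax(Xl2, st)
        used[seq] = st
    return out, used


class FeatureStandardizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying L2 row then MinMax column scaling.

    Operates on a single 2-D matrix; multisequence pipelines hold one
    instance per sequence (see :func:`standardize`).
    """

    def fit(self, X, y=None):
        Xl2 = l2_normalize_rows(np.asarray(X, dtype=float))
        self.state_ = fit_minmax_columns(Xl2)
        self.n_features_in_ = Xl2.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "state_"):
            raise RuntimeError("FeatureStandardizer is not fitted")
        return apply_minmax(l2_normalize_rows(np.asarray(X, dtype=float)),
                            self.state_)
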