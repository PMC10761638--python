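"""Lesion-to-patient aggregation and the evaluation / ablation protocol.

Patient-wise probabilities are the plain average of the patient's lesion
probability vectors, renormalized to unit L1 norm.  Performance is reported
per class as one-vs-rest AUC with a bootstrap 95% CI halfwidth (2,000
resamples of patients by default, lesions carried with their patient),
sensitivity/specificity/accuracy from the 3x3 confusion matrix, overall
accuracy, and Cohen's kappa; paired models are compared with the DeLong test
(with a bootstrap-difference variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import RadioGCNClassifier
from .synthetic import CLASS_NAMES

__all__ = [
    "aggregate_patient", "aggregate_patients", "ovr_auc", "bootstrap_auc",
    "confusion_metrics", "cohens_kappa", "delong_compare", "evaluate_predictions",
    "run_ablation", "EvalReport",
]


def aggregate_patient(lesion_probs: np.ndarray) -> np.ndarray:
    """Patient probability vector: mean over lesions, then L1 renormalized.

    ``p_m = (1/N) sum_i l_i^m`` followed by ``p <- p / ||p||_1``.
    """
    L = np.atleast_2d(np.asarray(lesion_probs, dtype=float))
    if L.shape[0] == 0:
        raise ValueError("a patient needs at least one lesion")
    p = L.mean(axis=0)
    s = np.abs(p).sum()
    if s == 0:
        raise ValueError("degenerate all-zero probability vectors")
    return p / s


def aggregate_patients(lesion_probs: np.ndarray, patient_ids
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate every patient; returns (unique patient ids, prob matrix)."""
    pids = np.asarray(patient_ids)
    uniq = pd.unique(pids)
    P = np.vstack([aggregate_patient(lesion_probs[pids == p]) for p in uniq])
    return uniq, P


def ovr_auc(labels, scores, positive_class=None) -> float:
    """One-vs-rest AUC = concordance probability with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == positive_class if positive_class is not None else labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_auc(labels, scores, B: int = 2000, seed: int = 0,
                  unit: str = "patient", patient_ids=None,
                  positive_class=None) -> tuple[float, float]:
    """Bootstrap mean AUC and 95% percentile-CI halfwidth.

    With ``unit="patient"`` resampling draws patients with replacement and
    carries all their lesions (preserving within-patient correlation);
    ``unit="lesion"`` resamples rows directly.  Resamples missing a class are
    redrawn.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == positive_class if positive_class is not None else labels.astype(bool)
    rng = np.random.default_rng(seed)

    if unit == "patient":
        if patient_ids is None:
            raise ValueError("patient-unit bootstrap needs patient_ids")
        pids = np.asarray(patient_ids)
        uniq = pd.unique(pids)
        groups = [np.nonzero(pids == p)[0] for p in uniq]
        n_units = len(uniq)
    elif unit == "lesion":
        groups = [np.array([i]) for i in range(len(labels))]
        n_units = len(labels)
    else:
        raise ValueError("unit must be 'patient' or 'lesion'")

    aucs = np.empty(B)
    for b in range(B):
        while True:
            pick = rng.integers(0, n_units, size=n_units)
            idx = np.concatenate([groups[i] for i in pick])
            if pos[idx].any() and (~pos[idx]).any():
                break
        aucs[b] = ovr_auc(pos[idx], scores[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(aucs.mean()), float((hi - lo) / 2.0)


def confusion_metrics(y_true, y_pred, classes=CLASS_NAMES) -> dict:
    """Per-class one-vs-rest sensitivity/specificity/accuracy + overall."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    classes = list(classes)
    M = np.zeros((len(classes), len(classes)), dtype=int)
    ci = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        M[ci[t], ci[p]] += 1
    total = M.sum()
    out = {"confusion_matrix": M, "overall_accuracy": float(np.trace(M) / total),
           "per_class": {}}
    for i, c in enumerate(classes):
        tp = M[i, i]
        fn = M[i].sum() - tp
        fp = M[:, i].sum() - tp
        tn = total - tp - fn - fp
        out["per_class"][c] = {
            "sensitivity": float(tp / (tp + fn)) if tp + fn else float("nan"),
            "specificity": float(tn / (tn + fp)) if tn + fp else float("nan"),
            "accuracy": float((tp + tn) / total),
        }
    return out


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement; defined as 1 when both margins are a
    single identical class (p_e = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.union1d(y_true, y_pred)
    n = len(y_true)
    po = float(np.mean(y_true == y_pred))
    pe = sum(np.mean(y_true == c) * np.mean(y_pred == c) for c in classes)
    if pe == 1.0:
        return 1.0
    return float((po - pe) / (1.0 - pe))


# ---------------------------------------------------------------------------
# DeLong test


def _midrank(x):
    return stats.rankdata(x, method="average")


def _delong_components(pos_scores, neg_scores):
    m, n = len(pos_scores), len(neg_scores)
    alls = np.concatenate([pos_scores, neg_scores])
    r = _midrank(alls)
    rx = _midrank(pos_scores)
    ry = _midrank(neg_scores)
    auc = (r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r[:m] - rx) / n                 # per-positive structural component
    v01 = 1.0 - (r[m:] - ry) / m           # per-negative structural component
    return auc, v10, v01


def delong_compare(scores_a, scores_b, labels, positive_class=None,
                   method: str = "delong", B: int = 2000, seed: int = 0
                   ) -> tuple[float, float]:
    """Difference of paired AUCs and its two-sided p-value.

    ``method="delong"`` uses the classic variance of the paired AUC
    difference for correlated ROC curves; ``method="bootstrap"`` resamples
    units with replacement ``B`` times and reads the p-value off the
    bootstrap distribution of the difference.
    """
    labels = np.asarray(labels)
    pos = labels == positive_class if positive_class is not None else labels.astype(bool)
    if not pos.any() or pos.all():
        raise ValueError("DeLong comparison needs both classes")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)

    auc_a, va10, va01 = _delong_components(sa[pos], sa[~pos])
    auc_b, vb10, vb01 = _delong_components(sb[pos], sb[~pos])
    diff = float(auc_a - auc_b)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(labels)
        diffs = np.empty(B)
        for b in range(B):
            while True:
                idx = rng.integers(0, n, size=n)
                if pos[idx].any() and (~pos[idx]).any():
                    break
            diffs[b] = ovr_auc(pos[idx], sa[idx]) - ovr_auc(pos[idx], sb[idx])
        p_lo = np.mean(diffs <= 0)
        p_hi = np.mean(diffs >= 0)
        return diff, float(min(1.0, 2.0 * min(p_lo, p_hi)))

    m, n_neg = int(pos.sum()), int((~pos).sum())
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n_neg > 1 else np.zeros((2, 2))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg)
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return diff, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# full evaluation and the ablation grid


@dataclass
class EvalReport:
    """Tidy table of evaluation rows plus raw per-variant metric dicts."""

    table: pd.DataFrame
    details: dict

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def to_json(self, path=None):
        js = self.table.to_json(orient="records", indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(js)
        return js


def evaluate_predictions(y_true, lesion_probs, patient_ids,
                         classes=CLASS_NAMES, B: int = 2000, seed: int = 0
                         ) -> dict:
    """Lesion-wise and patient-wise metrics for one model's predictions."""
    y_true = np.asarray(y_true)
    probs = np.asarray(lesion_probs, dtype=float)
    pids = np.asarray(patient_ids)
    classes = list(classes)

    uniq, P = aggregate_patients(probs, pids)
    pt_label = pd.Series(y_true, index=pids).groupby(level=0).first()
    y_pt = pt_label.loc[uniq].to_numpy()

    out = {}
    for wise, (yt, pr, ids) in {
        "lesion": (y_true, probs, pids),
        "patient": (y_pt, P, uniq),
    }.items():
        pred = np.array(classes)[np.argmax(pr, axis=1)]
        cm = confusion_metrics(yt, pred, classes)
        entry = {"overall_accuracy": cm["overall_accuracy"],
                 "kappa": cohens_kappa(yt, pred), "per_class": {}}
        for j, c in enumerate(classes):
            mean_auc, half = bootstrap_auc(
                yt == c, pr[:, j], B=B, seed=seed + 17 * j,
                unit="patient", patient_ids=ids)
            entry["per_class"][c] = {
                "auc": ovr_auc(yt == c, pr[:, j]),
                "auc_bootstrap_mean": mean_auc,
                "auc_ci_halfwidth": half,
                **cm["per_class"][c],
            }
        entry["macro_auc"] = float(np.mean(
            [entry["per_class"][c]["auc"] for c in classes]))
        out[wise] = entry
    return out


VARIANTS = ("gcn", "stand_gcn", "full")
SEQUENCE_SETS = {"t1ce": [0], "other_three": [1, 2, 3], "all_four": [0, 1, 2, 3]}


def _variant_params(variant: str) -> dict:
    return {
        "gcn": {"use_standardization": False, "use_attention": False},
        "stand_gcn": {"use_standardization": True, "use_attention": False},
        "full": {"use_standardization": True, "use_attention": True},
    }[variant]


def run_ablation(dataset: dict, seed: int = 0, B: int = 2000,
                 variants=VARIANTS, sequence_sets=None,
                 hyperparams: dict | None = None) -> EvalReport:
    """Train and evaluate the component x sequence-set ablation grid.

    ``dataset`` holds ``sequences`` (ordered names) and, for each of
    ``train``/``test``: ``X`` (n, K*d), ``y``, ``patient_ids``.  A K=1
    sequence set degenerates the attention stage to identity but keeps the
    single code path.
    """
    sequence_sets = dict(sequence_sets or SEQUENCE_SETS)
    hyperparams = dict(hyperparams or {})
    seqs = list(dataset["sequences"])
    K = len(seqs)
    d = dataset["train"]["X"].shape[1] // K

    def take(X, idx):
        B3 = np.asarray(X, dtype=float).reshape(len(X), K, d)
        return B3[:, idx, :].reshape(len(X), len(idx) * d)

    rows, details = [], {}
    for set_name, idx in sequence_sets.items():
        Xtr = take(dataset["train"]["X"], idx)
        Xte = take(dataset["test"]["X"], idx)
        for variant in variants:
            clf = RadioGCNClassifier(n_sequences=len(idx), seed=seed,
                                     **_variant_params(variant), **hyperparams)
            clf.fit(Xtr, dataset["train"]["y"],
                    patient_ids=dataset["train"]["patient_ids"])
            probs = clf.predict_proba(Xte)
            res = evaluate_predictions(dataset["test"]["y"], probs,
                                       dataset["test"]["patient_ids"],
                                       classes=clf.classes_, B=B, seed=seed)
            details[(variant, set_name)] = res
            for wise in ("lesion", "patient"):
                for c, met in res[wise]["per_class"].items():
                    rows.append({
                        "variant": variant, "sequences": set_name,
                        "wise": wise, "class": c,
                        "auc": met["auc"],
                        "auc_ci_halfwidth": met["auc_ci_halfwidth"],
                        "sensitivity": met["sensitivity"],
                        "specificity": met["specificity"],
                        "accuracy": met["accuracy"],
                        "overall_accuracy": res[wise]["overall_accuracy"],
                        "macro_auc": res[wise]["macro_auc"],
                        "kappa": res[wise]["kappa"],
                    })
    return EvalReport(table=pd.DataFrame(rows), details=details)
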