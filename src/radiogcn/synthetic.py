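"""Synthetic cohorts and image phantoms for exercising the full pipeline.

Two generators are provided:

* :func:`simulate_cohort` draws per-sequence radiomics *feature tables* for a
  three-class cohort (EGFR 19Del / 21L858R / WT) in which patients carry a
  variable number of brain-metastasis lesions.  Class signal is a Gaussian
  mean shift restricted to per-sequence *informative* feature indices, so
  multisequence fusion is genuinely rewarded when those sets are disjoint.
* :func:`simulate_phantom` builds small co-registered 3-D volumes with an
  ellipsoidal lesion, feeding the image-preprocessing / feature-extraction
  stage.

Both are exactly reproducible from their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CLASS_NAMES = ("19Del", "21L858R", "WT")
DEFAULT_SEQUENCES = ("T1-CE", "T2W", "T2-FLAIR", "DWI")

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_SEQUENCES",
    "CohortSpec",
    "PhantomSpec",
    "simulate_cohort",
    "simulate_phantom",
    "make_patient_folds",
]


def _default_informative_sets(n_features: int, n_sequences: int, per_seq: int = 64):
    """Disjoint blocks of informative indices, one block per sequence."""
    sets = []
    for k in range(n_sequences):
        start = k * per_seq
        sets.append(tuple(range(start, min(start + per_seq, n_features))))
    return sets


@dataclass
class CohortSpec:
    """Parameters of the synthetic three-class lesion cohort.

    Attributes
    ----------
    n_patients_per_class
        Patients in each of the classes ``("19Del", "21L858R", "WT")``.
    lesions_per_patient
        ``(min, max, probabilities)`` for the per-patient lesion count; with
        ``probabilities=None`` the count is uniform on ``[min, max]``.
    n_features
        Feature-vector dimension per sequence (the shipped registry has 1290).
    sequences
        Ordered MRI sequence names; the first is the T1-CE anchor.
    informative_sets
        Per sequence, the feature indices that carry class signal.  Defaults
        to disjoint 16-index blocks so no single sequence holds all signal.
    effect_size
        Class mean shift on informative indices, in units of ``noise_sd``.
    noise_sd
        Standard deviation of the shared diagonal Gaussian noise.
    scale_sigma
        Log-normal sigma of per-feature column scales.  Real radiomics
        features span orders of magnitude; a nonzero value reproduces that
        spread.
    sequence_scales
        Global intensity scale per sequence (default cycles 1, 30, 0.2, 8),
        mimicking the very different units/dynamic ranges of T1-CE, T2W,
        FLAIR and DWI derived features.  Without standardization, the
        largest-scale sequence dominates any concatenation or similarity —
        this is what the standardization stage corrects.
    corruption_rate, corruption_factor
        With probability ``corruption_rate`` a lesion has one randomly chosen
        sequence corrupted (think motion/susceptibility artifact): its class
        signal is wiped and its noise amplified by ``corruption_factor``.
        Per-lesion attention can learn to downweight the corrupted sequence;
        a fixed concatenation cannot.
    pattern_seed
        Seed of the class-signature patterns only.  Kept separate from
        ``seed`` so that train and test cohorts drawn with different sampling
        seeds share the same class-conditional structure.
    seed
        Sampling seed (patients, lesion counts, noise).
    """

    n_patients_per_class: tuple[int, int, int] = (30, 30, 30)
    lesions_per_patient: tuple[int, int, tuple | None] = (1, 4, None)
    n_features: int = 1290
    sequences: tuple[str, ...] = DEFAULT_SEQUENCES
    informative_sets: tuple[tuple[int, ...], ...] | None = None
    effect_size: float = 2.0
    noise_sd: float = 1.0
    scale_sigma: float = 1.0
    sequence_scales: tuple[float, ...] | None = None
    corruption_rate: float = 0.25
    corruption_factor: float = 4.0
    pattern_seed: int = 0
    seed: int = 0

    def __post_init__(self):
        if len(self.n_patients_per_class) != len(CLASS_NAMES):
            raise ValueError("n_patients_per_class must have one entry per class")
        if any(int(n) < 1 for n in self.n_patients_per_class):
            raise ValueError("n_patients_per_class entries must all be >= 1")
        lo, hi, probs = self.lesions_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("lesions_per_patient must satisfy 1 <= min <= max")
        if probs is not None:
            probs = np.asarray(probs, dtype=float)
            if probs.size != hi - lo + 1 or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
                raise ValueError("lesion-count probabilities must be a distribution over [min, max]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.informative_sets is None:
            self.informative_sets = tuple(
                _default_informative_sets(self.n_features, len(self.sequences))
            )
        if len(self.informative_sets) != len(self.sequences):
            raise ValueError("one informative set per sequence is required")
        for s in self.informative_sets:
            idx = np.asarray(s, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_features):
                raise ValueError("informative indices must lie in [0, n_features)")
        if self.sequence_scales is None:
            base = (1.0, 30.0, 0.2, 8.0)
            self.sequence_scales = tuple(base[k % 4] for k in range(len(self.sequences)))
        if len(self.sequence_scales) != len(self.sequences):
            raise ValueError("one sequence scale per sequence is required")
        if any(s <= 0 for s in self.sequence_scales):
            raise ValueError("sequence scales must be positive")
        if not (0 <= self.corruption_rate <= 1):
            raise ValueError("corruption_rate must lie in [0, 1]")
        if self.corruption_factor < 1:
            raise ValueError("corruption_factor must be >= 1")


@dataclass
class PhantomSpec:
    """Geometry and intensity of an ellipsoidal-lesion image phantom.

    Lengths are in millimetres; the lesion must lie fully inside the volume.
    """

    volume_shape: tuple[int, int, int] = (20, 64, 64)
    voxel_spacing: tuple[float, float, float] = (3.0, 0.25, 0.25)
    lesion_center: tuple[float, float, float] | None = None
    lesion_radii: tuple[float, float, float] = (6.0, 4.0, 4.0)
    background_level: float = 20.0
    lesion_level: float = 120.0
    texture_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if any(r <= 0 for r in self.lesion_radii):
            raise ValueError("lesion radii must be positive")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")
        extent = tuple(n * s for n, s in zip(self.volume_shape, self.voxel_spacing))
        if self.lesion_center is None:
            self.lesion_center = tuple(e / 2.0 for e in extent)
        for c, r, e in zip(self.lesion_center, self.lesion_radii, extent):
            if c - r < 0 or c + r > e:
                raise ValueError("lesion ellipsoid must lie fully inside the volume")


def _class_patterns(spec: CohortSpec) -> list[np.ndarray]:
    """Per-sequence (n_classes, n_features) mean matrices.

    Sequence ``k`` singles out class ``k % 3``: that class gets its own
    random +/-1 signature on the sequence's informative indices while the
    other two classes share a second signature.  Any single sequence can
    therefore separate only one class from the rest; all three classes are
    separable only by combining sequences, which is what rewards fusion.
    Patterns are drawn from ``pattern_seed`` only, so cohorts with different
    sampling seeds share class structure.
    """
    rng = np.random.default_rng(spec.pattern_seed)
    mats = []
    for k in range(len(spec.sequences)):
        mu = np.zeros((len(CLASS_NAMES), spec.n_features))
        idx = np.asarray(spec.informative_sets[k], dtype=int)
        if idx.size:
            own = rng.choice([-1.0, 1.0], size=idx.size)
            shared = rng.choice([-1.0, 1.0], size=idx.size)
            singled = k % len(CLASS_NAMES)
            for c in range(len(CLASS_NAMES)):
                sig = own if c == singled else shared
                mu[c, idx] = sig * spec.effect_size * spec.noise_sd
        mats.append(mu)
    return mats


def _column_scales(spec: CohortSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.pattern_seed + 1)
    if spec.scale_sigma == 0:
        return np.ones(spec.n_features)
    return rng.lognormal(mean=0.0, sigma=spec.scale_sigma, size=spec.n_features)


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw a synthetic cohort.

    Returns
    -------
    tables
        ``{sequence_name: DataFrame}`` with one row per lesion and columns
        ``patient_id, lesion_id, label, f0000, f0001, ...`` in registry order.
    manifest
        One row per lesion: ``patient_id, lesion_id, label``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi, probs = spec.lesions_per_patient
    counts_support = np.arange(lo, hi + 1)
    p = None if probs is None else np.asarray(probs, dtype=float)

    patients, labels, lesion_counts = [], [], []
    for c, cname in enumerate(CLASS_NAMES):
        for i in range(spec.n_patients_per_class[c]):
            patients.append(f"P{cname}-{i:03d}")
            labels.append(cname)
            lesion_counts.append(int(rng.choice(counts_support, p=p)))

    rows = []
    for pid, lab, n_les in zip(patients, labels, lesion_counts):
        for j in range(n_les):
            rows.append((pid, f"{pid}-L{j}", lab))
    manifest = pd.DataFrame(rows, columns=["patient_id", "lesion_id", "label"])
    class_idx = manifest["label"].map({c: i for i, c in enumerate(CLASS_NAMES)}).to_numpy()

    mus = _class_patterns(spec)
    scales = _column_scales(spec)
    n_lesions = len(manifest)
    feat_cols = [f"f{j:04d}" for j in range(spec.n_features)]

    # per-lesion artifact model: at most one corrupted sequence per lesion;
    # the artifact swaps in another class's signature (misleading contrast)
    # with amplified noise, so it is detectable but not ignorable by any
    # per-sequence weighting that is fixed across lesions
    corrupt_seq = np.full(n_lesions, -1)
    hit = rng.random(n_lesions) < spec.corruption_rate
    corrupt_seq[hit] = rng.integers(0, len(spec.sequences), size=int(hit.sum()))
    wrong_class = (class_idx + rng.integers(1, len(CLASS_NAMES), size=n_lesions)) \
        % len(CLASS_NAMES)

    tables = {}
    for k, seq in enumerate(spec.sequences):
        noise = rng.normal(0.0, spec.noise_sd, size=(n_lesions, spec.n_features))
        mu = mus[k][class_idx].copy()
        bad = corrupt_seq == k
        mu[bad] = mus[k][wrong_class[bad]]
        noise[bad] *= spec.corruption_factor
        X = (mu + noise) * scales * spec.sequence_scales[k]
        tables[seq] = pd.concat(
            [manifest.copy(),
             pd.DataFrame(X, columns=feat_cols, index=manifest.index)],
            axis=1)
    return tables, manifest


def simulate_phantom(spec: PhantomSpec):
    """Build four co-registered volumes plus an ellipsoidal lesion mask.

    The mask is exactly the set of voxels whose physical (mm) centre
    coordinates satisfy the ellipsoid inequality
    ``sum(((x_i - c_i) / r_i)**2) <= 1``.

    Returns ``(volumes, mask)`` where ``volumes`` maps sequence name to an
    :class:`~radiogcn.preprocess.ImageVolume` and ``mask`` is a
    :class:`~radiogcn.preprocess.LesionMask`.
    """
    from .preprocess import ImageVolume, LesionMask

    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.volume_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    center = np.asarray(spec.lesion_center, dtype=float)
    radii = np.asarray(spec.lesion_radii, dtype=float)

    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask_arr = (q <= 1.0).astype(np.uint8)

    volumes = {}
    for seq in DEFAULT_SEQUENCES:
        base = np.full(shape, spec.background_level, dtype=float)
        base[mask_arr == 1] = spec.lesion_level
        if spec.texture_sd > 0:
            base = base + rng.normal(0.0, spec.texture_sd, size=shape)
        volumes[seq] = ImageVolume(values=base, spacing=tuple(spacing))
    mask = LesionMask(values=mask_arr, spacing=tuple(spacing))
    return volumes, mask


def make_patient_folds(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Class-stratified, patient-disjoint fold assignment.

    All lesions of a patient share a fold; within each class, per-fold patient
    counts differ by at most one.

    Returns a DataFrame ``patient_id, label, fold``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = manifest[["patient_id", "label"]].drop_duplicates().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    out = []
    for cname in pts["label"].unique():
        ids = pts.loc[pts["label"] == cname, "patient_id"].to_numpy()
        if len(ids) < k:
            raise ValueError(f"class {cname!r} has fewer patients ({len(ids)}) than folds ({k})")
        ids = ids[rng.permutation(len(ids))]
        folds = np.arange(len(ids)) % k
        out.append(pd.DataFrame({"patient_id": ids, "label": cname, "fold": folds}))
    return pd.concat(out, ignore_index=True)
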