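"""The canonical radiomics feature registry.

The default extraction configuration enumerates, in a fixed canonical order:

* 107 original-image features: 14 shape, 18 first-order, 24 GLCM, 16 GLRLM,
  16 GLSZM, 5 NGTDM, 14 GLDM;
* 93 non-shape features (first-order + the five texture families) for each of
  the 8 single-level stationary-wavelet sub-bands (LLL ... HHH);
* the same 93 for each Laplacian-of-Gaussian response at sigma = 1..5 mm.

That enumeration yields 1,316 names; the shipped registry truncates it to the
first 1,290 in canonical order.  The truncation point was reverse-engineered
to match the feature count the model was designed around — the exact filter
bank behind that count is not canonical, so the registry, not the bank, is
the contract: its length and order are stable and hash-checked everywhere a
model bundle or scaler is applied.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)
FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_FEATURES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

FEATURE_CLASSES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "gldm": GLDM_FEATURES,
}
NONSHAPE_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)

DEFAULT_REGISTRY_SIZE = 1290

__all__ = [
    "RegistryEntry", "FeatureRegistry", "build_feature_registry",
    "FEATURE_CLASSES", "NONSHAPE_CLASSES", "WAVELET_SUBBANDS",
    "LOG_SIGMAS_MM", "DEFAULT_REGISTRY_SIZE",
]


@dataclass(frozen=True)
class RegistryEntry:
    image_type: str      # "original", "wavelet-LLH", "log-sigma-3-mm"
    feature_class: str   # "shape", "firstorder", "glcm", ...
    feature_name: str

    @property
    def name(self) -> str:
        return f"{self.image_type}_{self.feature_class}_{self.feature_name}"


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, hash-stable list of feature names."""

    entries: tuple[RegistryEntry, ...]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        if not names:
            raise ValueError("empty feature registry")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def sha256(self) -> str:
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()

    def image_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.image_type, None)
        return list(seen)


def _enumerate(image_types: list[str], classes_for) -> list[RegistryEntry]:
    out = []
    for it in image_types:
        for cls in classes_for(it):
            for name in FEATURE_CLASSES[cls]:
                out.append(RegistryEntry(it, cls, name))
    return out


def build_feature_registry(config: dict | None = None) -> FeatureRegistry:
    """Build the registry from an extraction configuration.

    ``config`` keys (all optional):

    * ``image_types``: list of image types, default original + 8 wavelet
      sub-bands + 5 LoG sigmas;
    * ``feature_classes``: enabled classes, default all seven (shape is only
      ever computed on the original image);
    * ``max_features``: truncate the canonical enumeration, default 1290
      (``None`` disables truncation).

    The default configuration yields exactly 1,290 entries.
    """
    config = dict(config or {})
    image_types = config.pop("image_types", None)
    classes = tuple(config.pop("feature_classes", FEATURE_CLASSES))
    max_features = config.pop("max_features", DEFAULT_REGISTRY_SIZE)
    if config:
        raise ValueError(f"unknown registry config keys: {sorted(config)}")
    unknown = set(classes) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    if not classes:
        raise ValueError("at least one feature class must be enabled")
    if image_types is None:
        image_types = (
            ["original"]
            + [f"wavelet-{b}" for b in WAVELET_SUBBANDS]
            + [f"log-sigma-{sig:g}-mm" for sig in LOG_SIGMAS_MM]
        )
    if not image_types:
        raise ValueError("at least one image type must be enabled")

    def classes_for(image_type: str):
        # shape is geometry-only: original image only, listed first there
        ordered = [c for c in ("shape",) + NONSHAPE_CLASSES if c in classes]
        if image_type != "original":
            ordered = [c for c in ordered if c != "shape"]
        return ordered

    entries = _enumerate(list(image_types), classes_for)
    if max_features is not None:
        entries = entries[:max_features]
    return FeatureRegistry(entries=tuple(entries))
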