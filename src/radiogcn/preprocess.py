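"""MRI preprocessing: lesion-size filtering, resampling, cropping, rescaling.

The preprocessing chain applied to every lesion before feature extraction is

    resample (3 x 0.25 x 0.25 mm) -> crop to mask bounding box -> MinMax
    rescale to [0, 255]

Volumes are kept in a lightweight geometry-aware container; resampling is
delegated to SimpleITK (linear for images, nearest-neighbour for masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

DEFAULT_SPACING = (3.0, 0.25, 0.25)
MIN_LESION_DIAMETER_MM = 5.0

__all__ = [
    "ImageVolume",
    "LesionMask",
    "filter_lesions",
    "lesion_diameter_mm",
    "resample_volume",
    "crop_to_bbox",
    "rescale_intensity",
    "DEFAULT_SPACING",
    "MIN_LESION_DIAMETER_MM",
]


@dataclass
class ImageVolume:
    """A 3-D scalar volume with physical geometry (axis order z, y, x)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self):
        return self.values.shape

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.asarray(self.values, dtype=np.float64))
        img.SetSpacing(tuple(self.spacing[::-1]))  # sitk is x,y,z ordered
        img.SetOrigin(tuple(self.origin[::-1]))
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(
            values=sitk.GetArrayFromImage(img),
            spacing=tuple(img.GetSpacing()[::-1]),
            origin=tuple(img.GetOrigin()[::-1]),
            direction=tuple(img.GetDirection()),
        )


@dataclass
class LesionMask(ImageVolume):
    """Binary lesion mask sharing an ImageVolume's grid."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.values = vals.astype(np.uint8)


def lesion_diameter_mm(mask: LesionMask) -> float:
    """Maximum per-axis physical extent of the mask bounding box (mm).

    A cheap, monotone surrogate for the true maximum 3-D diameter.
    """
    idx = np.nonzero(mask.values)
    if idx[0].size == 0:
        raise ValueError("empty mask has no diameter")
    extents = [
        (ax.max() - ax.min() + 1) * s for ax, s in zip(idx, mask.spacing)
    ]
    return float(max(extents))


def filter_lesions(manifest: pd.DataFrame,
                   min_diameter_mm: float = MIN_LESION_DIAMETER_MM) -> pd.DataFrame:
    """Drop lesions below the minimum diameter.

    ``manifest`` must carry a ``diameter_mm`` column (from
    :func:`lesion_diameter_mm`).  Retains exactly the lesions with
    ``diameter_mm >= min_diameter_mm``: a 5.0 mm lesion stays, 4.9 mm goes.
    """
    if "diameter_mm" not in manifest.columns:
        raise ValueError("manifest must contain a 'diameter_mm' column")
    if manifest["diameter_mm"].isna().any():
        raise ValueError("missing lesion diameter (mask not found?)")
    return manifest.loc[manifest["diameter_mm"] >= min_diameter_mm].reset_index(drop=True)


def resample_volume(img: ImageVolume,
                    target_spacing: tuple[float, float, float] = DEFAULT_SPACING,
                    mode: str = "linear") -> ImageVolume:
    """Resample onto an isotropic-per-axis grid at ``target_spacing`` (mm).

    Output size per axis is ``round(n_in * spacing_in / spacing_out)`` so the
    physical extent is preserved to within one voxel.  ``mode`` is ``linear``
    for images, ``nearest`` for masks.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    if tuple(img.spacing) == tuple(target_spacing):
        return img
    src = img.to_sitk()
    in_size = np.asarray(src.GetSize(), dtype=float)        # x,y,z
    in_sp = np.asarray(src.GetSpacing(), dtype=float)
    out_sp = np.asarray(target_spacing[::-1], dtype=float)
    out_size = np.maximum(1, np.round(in_size * in_sp / out_sp)).astype(int)

    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[mode]
    res = sitk.Resample(
        src,
        [int(n) for n in out_size],
        sitk.Transform(),
        interp,
        src.GetOrigin(),
        [float(s) for s in out_sp],
        src.GetDirection(),
        0.0,
        src.GetPixelID(),
        True,  # nearest-neighbour extrapolation at the half-voxel border
    )
    out = ImageVolume.from_sitk(res)
    if isinstance(img, LesionMask):
        return LesionMask(values=np.rint(out.values).astype(np.uint8),
                          spacing=out.spacing, origin=out.origin,
                          direction=out.direction)
    return out


def crop_to_bbox(img: ImageVolume, mask: LesionMask,
                 margin_voxels: int = 0) -> tuple[ImageVolume, LesionMask]:
    """Crop image and mask to the mask's tight bounding box plus a margin.

    The margin is clipped at the volume border.
    """
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    idx = np.nonzero(mask.values)
    if idx[0].size == 0:
        raise ValueError("cannot crop to an empty mask")
    slices = []
    for ax, n in zip(idx, img.shape):
        lo = max(int(ax.min()) - margin_voxels, 0)
        hi = min(int(ax.max()) + margin_voxels + 1, n)
        slices.append(slice(lo, hi))
    origin = tuple(
        o + s.start * sp for o, s, sp in zip(img.origin, slices, img.spacing)
    )
    patch = ImageVolume(values=img.values[tuple(slices)].copy(),
                        spacing=img.spacing, origin=origin,
                        direction=img.direction)
    patch_mask = LesionMask(values=mask.values[tuple(slices)].copy(),
                            spacing=mask.spacing, origin=origin,
                            direction=mask.direction)
    return patch, patch_mask


def rescale_intensity(patch: ImageVolume) -> ImageVolume:
    """MinMax-rescale a patch to [0, 255].

    ``x -> 255 * (x - min) / (max - min)``; a constant patch maps to all
    zeros (no texture to preserve, and it avoids a 0/0).
    """
    vals = np.asarray(patch.values, dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out = np.zeros_like(vals)
    else:
        out = 255.0 * (vals - lo) / (hi - lo)
    return ImageVolume(values=out, spacing=patch.spacing,
                       origin=patch.origin, direction=patch.direction)
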