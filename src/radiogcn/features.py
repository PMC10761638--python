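"""Radiomics feature computation on preprocessed lesion patches.

Implements the standard (IBSI-aligned) definitions of first-order, shape and
the five gray-level texture families (GLCM, GLRLM, GLSZM, NGTDM, GLDM) in
numpy/scipy, plus the wavelet and Laplacian-of-Gaussian filter bank of the
default registry.  Gray levels are discretized with a fixed bin count of 32;
texture matrices use the 13 unique 3-D directions (GLCM/GLRLM, feature values
averaged over directions) and 26-connectivity (GLSZM/NGTDM/GLDM).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .preprocess import ImageVolume, LesionMask
from .registry import (FEATURE_CLASSES, FeatureRegistry, LOG_SIGMAS_MM,
                       WAVELET_SUBBANDS)

BIN_COUNT = 32
_EPS = np.finfo(float).eps

# 13 unique direction vectors covering the 26-neighbourhood up to sign
DIRECTIONS_3D = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

__all__ = ["extract_features", "discretize", "filtered_images", "BIN_COUNT"]


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int = BIN_COUNT):
    """Fixed-bin-count discretization of in-mask intensities to levels 1..Ng.

    Returns the level array (0 outside the mask) and the realized Ng.
    """
    out = np.zeros(values.shape, dtype=np.int64)
    inside = mask.astype(bool)
    v = values[inside]
    lo, hi = v.min(), v.max()
    if hi == lo:
        out[inside] = 1
        return out, 1
    edges = np.linspace(lo, hi, n_bins + 1)
    lev = np.digitize(v, edges[1:-1], right=False) + 1
    out[inside] = lev
    return out, n_bins


# ---------------------------------------------------------------------------
# first-order


def _firstorder(values, mask, spacing):
    x = values[mask.astype(bool)].astype(float)
    n = x.size
    voxvol = float(np.prod(spacing))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = x.mean()
    var = x.var()
    lev, ng = discretize(values, mask)
    counts = np.bincount(lev[mask.astype(bool)], minlength=ng + 1)[1:]
    p = counts / n
    pnz = p[p > 0]
    robust = x[(x >= p10) & (x <= p90)]
    sd = np.sqrt(var)
    skew = 0.0 if sd == 0 else float(np.mean((x - mean) ** 3) / sd ** 3)
    kurt = 3.0 if sd == 0 else float(np.mean((x - mean) ** 4) / var ** 2)
    return {
        "Energy": float(np.sum(x ** 2)),
        "TotalEnergy": float(voxvol * np.sum(x ** 2)),
        "Entropy": float(-np.sum(pnz * np.log2(pnz))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float(np.sum(p ** 2)),
    }


# ---------------------------------------------------------------------------
# shape


def _max_pairwise(coords):
    if len(coords) < 2:
        return 0.0
    if len(coords) > 400:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except QhullError:
            pass
    return float(pdist(coords).max())


def _shape(mask, spacing):
    m = mask.astype(np.uint8)
    n = int(m.sum())
    spacing = np.asarray(spacing, dtype=float)
    voxvol = float(np.prod(spacing))

    padded = np.pad(m, 1)
    verts, faces, _, _ = measure.marching_cubes(padded.astype(float), level=0.5,
                                                spacing=tuple(spacing))
    surface = float(measure.mesh_surface_area(verts, faces))
    # divergence-theorem mesh volume
    tri = verts[faces]
    mesh_vol = float(abs(np.einsum("ij,ij->", tri[:, 0],
                                   np.cross(tri[:, 1], tri[:, 2])) / 6.0))

    idx = np.column_stack(np.nonzero(m)).astype(float)
    phys = idx * spacing  # voxel centres in mm
    d3 = _max_pairwise(phys)
    d_slice = max((_max_pairwise(phys[idx[:, 0] == z][:, 1:])
                   for z in np.unique(idx[:, 0])), default=0.0)
    d_col = max((_max_pairwise(phys[idx[:, 1] == y][:, [0, 2]])
                 for y in np.unique(idx[:, 1])), default=0.0)
    d_row = max((_max_pairwise(phys[idx[:, 2] == x][:, [0, 1]])
                 for x in np.unique(idx[:, 2])), default=0.0)

    if n > 1:
        lam = np.linalg.eigvalsh(np.cov(phys.T))
        lam = np.clip(lam, 0, None)[::-1]  # major, minor, least
    else:
        lam = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(lam)).tolist()
    elong = float(np.sqrt(lam[1] / lam[0])) if lam[0] > 0 else 0.0
    flat = float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 0.0

    sphericity = ((36.0 * np.pi * mesh_vol ** 2) ** (1.0 / 3.0) / surface
                  if surface > 0 else 0.0)
    return {
        "MeshVolume": mesh_vol,
        "VoxelVolume": float(n * voxvol),
        "SurfaceArea": surface,
        "SurfaceVolumeRatio": surface / mesh_vol if mesh_vol > 0 else 0.0,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": d3,
        "Maximum2DDiameterSlice": d_slice,
        "Maximum2DDiameterColumn": d_col,
        "Maximum2DDiameterRow": d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elong,
        "Flatness": flat,
    }


# ---------------------------------------------------------------------------
# texture helpers


def _iter_lines(shape, delta):
    """Index arrays for every maximal lattice line along direction delta."""
    dz, dy, dx = delta
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    prev = (zz - dz, yy - dy, xx - dx)
    oob = np.zeros(shape, dtype=bool)
    for p, s in zip(prev, shape):
        oob |= (p < 0) | (p >= s)
    starts = np.column_stack(np.nonzero(oob))
    d = np.array(delta)
    n = np.array(shape)
    for s0 in starts:
        # line length until any coordinate leaves the grid
        steps = []
        for c, dd, nn in zip(s0, d, n):
            if dd > 0:
                steps.append((nn - 1 - c) // dd)
            elif dd < 0:
                steps.append(c // (-dd))
        length = int(min(steps)) + 1 if steps else 1
        t = np.arange(length)
        yield (s0[0] + t * d[0], s0[1] + t * d[1], s0[2] + t * d[2])


def _runs_along(levels, delta):
    """(gray level, run length) pairs for all runs along one direction."""
    gls, lens = [], []
    for line in _iter_lines(levels.shape, delta):
        v = levels[line]
        if v.size == 0:
            continue
        # split at level changes; level 0 = outside mask
        change = np.nonzero(np.diff(v))[0] + 1
        seg_starts = np.concatenate(([0], change))
        seg_ends = np.concatenate((change, [v.size]))
        for a, b in zip(seg_starts, seg_ends):
            if v[a] > 0:
                gls.append(int(v[a]))
                lens.append(int(b - a))
    return np.array(gls, dtype=int), np.array(lens, dtype=int)


def _shift(arr, delta, fill=0):
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(delta):
        if d > 0:
            src[ax] = slice(0, arr.shape[ax] - d)
            dst[ax] = slice(d, arr.shape[ax])
        elif d < 0:
            src[ax] = slice(-d, arr.shape[ax])
            dst[ax] = slice(0, arr.shape[ax] + d)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _offsets26():
    return [(dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)]


# ---------------------------------------------------------------------------
# GLCM


def _glcm_features(levels, ng):
    feats = {k: [] for k in FEATURE_CLASSES["glcm"]}
    i_idx, j_idx = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1),
                               indexing="ij")
    for delta in DIRECTIONS_3D:
        shifted = _shift(levels, delta)
        valid = (levels > 0) & (shifted > 0)
        a = levels[valid] - 1
        b = shifted[valid] - 1
        P = np.zeros((ng, ng))
        np.add.at(P, (a, b), 1.0)
        P = P + P.T  # symmetrize
        if P.sum() == 0:
            continue
        p = P / P.sum()
        px = p.sum(axis=1)
        mu = float(np.sum(i_idx[:, 0] * px))
        sig2 = float(np.sum((i_idx[:, 0] - mu) ** 2 * px))
        k_sum = np.arange(2, 2 * ng + 1)
        p_sum = np.array([p[(i_idx + j_idx) == k].sum() for k in k_sum])
        k_dif = np.arange(0, ng)
        p_dif = np.array([p[np.abs(i_idx - j_idx) == k].sum() for k in k_dif])

        pnz = p[p > 0]
        hxy = float(-np.sum(pnz * np.log2(pnz)))
        pxnz = px[px > 0]
        hx = float(-np.sum(pxnz * np.log2(pxnz)))
        pij_marg = np.outer(px, px)
        m1 = p > 0
        hxy1 = float(-np.sum(p[m1] * np.log2(pij_marg[m1] + _EPS)))
        m2 = pij_marg > 0
        hxy2 = float(-np.sum(pij_marg[m2] * np.log2(pij_marg[m2])))

        da = float(np.sum(k_dif * p_dif))
        corr = 1.0 if sig2 == 0 else float(
            (np.sum(i_idx * j_idx * p) - mu * mu) / sig2)

        # MCC: second-largest eigenvalue of the Markov-like transition matrix
        nzl = px > 0
        if nzl.sum() <= 1:
            mcc = 1.0
        else:
            psub = p[np.ix_(nzl, nzl)]
            pxs = px[nzl]
            Q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
            ev = np.sort(np.real(np.linalg.eigvals(Q)))
            mcc = float(np.sqrt(max(ev[-2], 0.0)))

        vals = {
            "Autocorrelation": float(np.sum(i_idx * j_idx * p)),
            "ClusterProminence": float(np.sum((i_idx + j_idx - 2 * mu) ** 4 * p)),
            "ClusterShade": float(np.sum((i_idx + j_idx - 2 * mu) ** 3 * p)),
            "ClusterTendency": float(np.sum((i_idx + j_idx - 2 * mu) ** 2 * p)),
            "Contrast": float(np.sum((i_idx - j_idx) ** 2 * p)),
            "Correlation": corr,
            "DifferenceAverage": da,
            "DifferenceEntropy": float(-np.sum(p_dif[p_dif > 0]
                                               * np.log2(p_dif[p_dif > 0]))),
            "DifferenceVariance": float(np.sum((k_dif - da) ** 2 * p_dif)),
            "Id": float(np.sum(p_dif / (1.0 + k_dif))),
            "Idm": float(np.sum(p_dif / (1.0 + k_dif ** 2))),
            "Idmn": float(np.sum(p_dif / (1.0 + (k_dif / ng) ** 2))),
            "Idn": float(np.sum(p_dif / (1.0 + k_dif / ng))),
            "Imc1": 0.0 if hx == 0 else float((hxy - hxy1) / hx),  # HX == HY by symmetry
            "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
            "InverseVariance": float(np.sum(p_dif[1:] / k_dif[1:] ** 2))
            if ng > 1 else 0.0,
            "JointAverage": mu,
            "JointEnergy": float(np.sum(p ** 2)),
            "JointEntropy": hxy,
            "MCC": mcc,
            "MaximumProbability": float(p.max()),
            "SumAverage": float(np.sum(k_sum * p_sum)),
            "SumEntropy": float(-np.sum(p_sum[p_sum > 0]
                                        * np.log2(p_sum[p_sum > 0]))),
            "SumSquares": sig2,
        }
        for k, v in vals.items():
            feats[k].append(v)
    return {k: float(np.mean(v)) if v else 0.0 for k, v in feats.items()}


# ---------------------------------------------------------------------------
# GLRLM


def _rl_style_features(gl, size, npix, kind):
    """Shared gray-level / size-weighted statistics for GLRLM and GLSZM."""
    ns = gl.size
    if ns == 0:
        return {k: 0.0 for k in FEATURE_CLASSES["glrlm" if kind == "run" else "glszm"]}
    glf = gl.astype(float)
    szf = size.astype(float)
    p = np.ones(ns) / ns
    mu_g = float(np.sum(glf) / ns)
    mu_s = float(np.sum(szf) / ns)
    # non-uniformities need grouped sums
    gl_counts = np.bincount(gl)[1:]
    sz_counts = np.bincount(size)[1:]
    gln = float(np.sum(gl_counts.astype(float) ** 2) / ns)
    szn = float(np.sum(sz_counts.astype(float) ** 2) / ns)
    joint = {}
    np_pairs = np.column_stack((gl, size))
    _, inv, cnt = np.unique(np_pairs, axis=0, return_inverse=True,
                            return_counts=True)
    pj = cnt / ns
    ent = float(-np.sum(pj * np.log2(pj)))
    common = dict(
        gln=gln, glnn=gln / ns, szn=szn, sznn=szn / ns,
        sre=float(np.mean(1.0 / szf ** 2)), lre=float(np.mean(szf ** 2)),
        lgl=float(np.mean(1.0 / glf ** 2)), hgl=float(np.mean(glf ** 2)),
        srlgl=float(np.mean(1.0 / (glf ** 2 * szf ** 2))),
        srhgl=float(np.mean(glf ** 2 / szf ** 2)),
        lrlgl=float(np.mean(szf ** 2 / glf ** 2)),
        lrhgl=float(np.mean(glf ** 2 * szf ** 2)),
        glvar=float(np.mean((glf - mu_g) ** 2)),
        svar=float(np.mean((szf - mu_s) ** 2)),
        entropy=ent, pct=ns / npix,
    )
    if kind == "run":
        return {
            "GrayLevelNonUniformity": common["gln"],
            "GrayLevelNonUniformityNormalized": common["glnn"],
            "GrayLevelVariance": common["glvar"],
            "HighGrayLevelRunEmphasis": common["hgl"],
            "LongRunEmphasis": common["lre"],
            "LongRunHighGrayLevelEmphasis": common["lrhgl"],
            "LongRunLowGrayLevelEmphasis": common["lrlgl"],
            "LowGrayLevelRunEmphasis": common["lgl"],
            "RunEntropy": common["entropy"],
            "RunLengthNonUniformity": common["szn"],
            "RunLengthNonUniformityNormalized": common["sznn"],
            "RunPercentage": common["pct"],
            "RunVariance": common["svar"],
            "ShortRunEmphasis": common["sre"],
            "ShortRunHighGrayLevelEmphasis": common["srhgl"],
            "ShortRunLowGrayLevelEmphasis": common["srlgl"],
        }
    return {
        "GrayLevelNonUniformity": common["gln"],
        "GrayLevelNonUniformityNormalized": common["glnn"],
        "GrayLevelVariance": common["glvar"],
        "HighGrayLevelZoneEmphasis": common["hgl"],
        "LargeAreaEmphasis": common["lre"],
        "LargeAreaHighGrayLevelEmphasis": common["lrhgl"],
        "LargeAreaLowGrayLevelEmphasis": common["lrlgl"],
        "LowGrayLevelZoneEmphasis": common["lgl"],
        "SizeZoneNonUniformity": common["szn"],
        "SizeZoneNonUniformityNormalized": common["sznn"],
        "SmallAreaEmphasis": common["sre"],
        "SmallAreaHighGrayLevelEmphasis": common["srhgl"],
        "SmallAreaLowGrayLevelEmphasis": common["srlgl"],
        "ZoneEntropy": common["entropy"],
        "ZonePercentage": common["pct"],
        "ZoneVariance": common["svar"],
    }


def _glrlm_features(levels, npix):
    per_dir = []
    for delta in DIRECTIONS_3D:
        gl, ln = _runs_along(levels, delta)
        per_dir.append(_rl_style_features(gl, ln, npix, kind="run"))
    keys = FEATURE_CLASSES["glrlm"]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


def _glszm_features(levels, ng, npix):
    structure = np.ones((3, 3, 3), dtype=int)
    gls, sizes = [], []
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(levels == g, structure=structure)
        if nlab:
            cnt = np.bincount(lab.ravel())[1:]
            gls.extend([g] * nlab)
            sizes.extend(cnt.tolist())
    return _rl_style_features(np.array(gls, dtype=int),
                              np.array(sizes, dtype=int), npix, kind="zone")


# ---------------------------------------------------------------------------
# NGTDM


def _ngtdm_features(levels, ng, mask):
    inside = mask.astype(bool)
    npix = int(inside.sum())
    nb_sum = np.zeros(levels.shape)
    nb_cnt = np.zeros(levels.shape)
    for off in _offsets26():
        sh = _shift(levels, off)
        valid = sh > 0
        nb_sum += np.where(valid, sh, 0)
        nb_cnt += valid
    has_nb = inside & (nb_cnt > 0)
    A = np.zeros(levels.shape)
    A[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    diffs = np.abs(levels - A)

    i = np.arange(1, ng + 1)
    n_i = np.array([int(((levels == g) & inside).sum()) for g in i])
    s_i = np.array([float(diffs[(levels == g) & has_nb].sum()) for g in i])
    p_i = n_i / npix
    nz = p_i > 0
    ngp = int(nz.sum())

    coarse_den = float(np.sum(p_i * s_i))
    coarseness = 1e6 if coarse_den == 0 else 1.0 / coarse_den

    if ngp <= 1:
        contrast = 0.0
        busy = 0.0
        strength = 0.0
        complexity = 0.0
    else:
        ii, jj = np.meshgrid(i[nz], i[nz], indexing="ij")
        pi, pj = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
        si, sj = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")
        contrast = (float(np.sum(pi * pj * (ii - jj) ** 2))
                    / (ngp * (ngp - 1))) * (float(s_i.sum()) / npix)
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busy = 0.0 if busy_den == 0 else coarse_den / busy_den
        complexity = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj)
                                  / (pi + pj))) / npix
        s_sum = float(s_i.sum())
        strength = (0.0 if s_sum == 0
                    else float(np.sum((pi + pj) * (ii - jj) ** 2)) / s_sum)
    return {"Busyness": busy, "Coarseness": coarseness,
            "Complexity": complexity, "Contrast": contrast,
            "Strength": strength}


# ---------------------------------------------------------------------------
# GLDM


def _gldm_features(levels, ng, mask, alpha: int = 0):
    inside = mask.astype(bool)
    npix = int(inside.sum())
    dep = np.zeros(levels.shape, dtype=int)
    for off in _offsets26():
        sh = _shift(levels, off)
        dep += ((sh > 0) & (np.abs(sh - levels) <= alpha)).astype(int)
    gl = levels[inside]
    dj = dep[inside] + 1  # dependence size includes the centre voxel
    D = np.zeros((ng, dj.max()))
    np.add.at(D, (gl - 1, dj - 1), 1.0)
    nd = float(D.sum())
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, D.shape[1] + 1, dtype=float)[None, :]
    p = D / nd
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    pnz = p[p > 0]
    dn = float(np.sum(D.sum(axis=0) ** 2) / nd)
    return {
        "DependenceEntropy": float(-np.sum(pnz * np.log2(pnz))),
        "DependenceNonUniformity": dn,
        "DependenceNonUniformityNormalized": dn / nd,
        "DependenceVariance": float(np.sum((j - mu_j) ** 2 * p)),
        "GrayLevelNonUniformity": float(np.sum(D.sum(axis=1) ** 2) / nd),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * p)),
        "HighGrayLevelEmphasis": float(np.sum(i ** 2 * p)),
        "LargeDependenceEmphasis": float(np.sum(j ** 2 * p)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(i ** 2 * j ** 2 * p)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(j ** 2 / i ** 2 * p)),
        "LowGrayLevelEmphasis": float(np.sum(p / i ** 2)),
        "SmallDependenceEmphasis": float(np.sum(p / j ** 2)),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(i ** 2 / j ** 2 * p)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (i ** 2 * j ** 2))),
    }


# ---------------------------------------------------------------------------
# filter bank


def filtered_images(values: np.ndarray, spacing) -> dict[str, np.ndarray]:
    """Original + wavelet sub-band + LoG response images, all same shape."""
    out = {"original": np.asarray(values, dtype=float)}

    # single-level stationary wavelet (coif1); pad each axis to even length
    arr = out["original"]
    pads = [(0, s % 2) for s in arr.shape]
    padded = np.pad(arr, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet="coif1", level=1)[0]
    crop = tuple(slice(0, s) for s in arr.shape)
    for band in WAVELET_SUBBANDS:
        key = band.replace("L", "a").replace("H", "d")
        out[f"wavelet-{band}"] = coeffs[key][crop]

    sp = np.asarray(spacing, dtype=float)
    for sig in LOG_SIGMAS_MM:
        out[f"log-sigma-{sig:g}-mm"] = ndimage.gaussian_laplace(
            arr, sigma=tuple(sig / sp))
    return out


# ---------------------------------------------------------------------------
# public entry point


def extract_features(patch: ImageVolume, patch_mask: LesionMask,
                     registry: FeatureRegistry) -> np.ndarray:
    """Compute one finite value per registry entry, in registry order."""
    if patch.shape != patch_mask.shape:
        raise ValueError("patch and mask shapes differ")
    mask = np.asarray(patch_mask.values)
    if mask.sum() == 0:
        raise ValueError("cannot extract features from an empty mask")

    needed_types = registry.image_types()
    images = filtered_images(patch.values, patch.spacing)
    cache: dict[tuple[str, str], dict] = {}

    def compute(image_type: str, fclass: str) -> dict:
        key = (image_type, fclass)
        if key in cache:
            return cache[key]
        if fclass == "shape":
            res = _shape(mask, patch.spacing)
        else:
            img = images[image_type]
            if fclass == "firstorder":
                res = _firstorder(img, mask, patch.spacing)
            else:
                levels, ng = discretize(img, mask)
                npix = int(mask.sum())
                if fclass == "glcm":
                    res = _glcm_features(levels, ng)
                elif fclass == "glrlm":
                    res = _glrlm_features(levels, npix)
                elif fclass == "glszm":
                    res = _glszm_features(levels, ng, npix)
                elif fclass == "ngtdm":
                    res = _ngtdm_features(levels, ng, mask)
                elif fclass == "gldm":
                    res = _gldm_features(levels, ng, mask)
                else:
                    raise ValueError(f"unknown feature class {fclass!r}")
        cache[key] = res
        return res

    vec = np.empty(len(registry), dtype=float)
    for idx, entry in enumerate(registry.entries):
        vec[idx] = compute(entry.image_type, entry.feature_class)[entry.feature_name]
    if not np.all(np.isfinite(vec)):
        bad = [registry.entries[i].name for i in np.nonzero(~np.isfinite(vec))[0]]
        raise FloatingPointError(f"non-finite features: {bad[:5]}")
    return vec
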