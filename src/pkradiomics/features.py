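"""Radiomic feature extraction: 9 shape + per image 13 first-order and
9 gray-level cooccurrence (GLCM) features.

With the full set of seven source images (R1, ktrans, kep, ve, iAUC,
TIRM-like and delayed-postcontrast) a lesion yields 9 + 7*22 = 163 named
features.  Intensity features are computed inside the tumor mask after
clipping the dynamics to mean +/- 3 sigma; first-order histogram statistics
use 256 bins, texture uses 32 gray levels and one direction-merged
symmetric GLCM over all 26 neighbor directions at distance 1.

Naming scheme: ``shape__<feature>`` and ``<image>__<feature>`` with
first-order names {energy, entropy, kurtosis, max, mean, mad, median, min,
rms, skewness, std, uniformity, variance} and texture names prefixed
``glcm_``.
"""

from __future__ import annotations

import numpy as np

from .segment import TumorMask
from .volume import GeometryError, ImageVolume

__all__ = ["normalize_intensities", "quantize", "shape_features",
           "first_order_features", "glcm_matrix", "glcm_features",
           "extract_all", "DegenerateMatrixError",
           "FIRST_ORDER_NAMES", "GLCM_NAMES", "SHAPE_NAMES", "IMAGE_NAMES"]

FIRST_ORDER_NAMES = ("energy", "entropy", "kurtosis", "max", "mean", "mad",
                     "median", "min", "rms", "skewness", "std", "uniformity",
                     "variance")
GLCM_NAMES = ("glcm_energy", "glcm_contrast", "glcm_entropy",
              "glcm_homogeneity", "glcm_correlation", "glcm_sum_average",
              "glcm_variance", "glcm_dissimilarity", "glcm_autocorrelation")
SHAPE_NAMES = ("n_voxels", "volume", "surface_area", "surface_volume_ratio",
               "max_diameter", "min_diameter", "compactness",
               "spherical_disproportion", "sphericity")
IMAGE_NAMES = ("r1", "ktrans", "kep", "ve", "iauc", "tirm", "postc")

# the 13 unique 3D neighbor directions (26-connectivity, symmetrized)
_DIRECTIONS = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) > (0, 0, 0)]


class DegenerateMatrixError(ValueError):
    """The mask admits no valid cooccurrence pairs."""


def normalize_intensities(image: ImageVolume, mask: TumorMask,
                          n_sigma: float = 3.0) -> np.ndarray:
    """Masked intensities clipped to [mu - n*sigma, mu + n*sigma].

    mu and sigma are the within-mask mean and population standard deviation
    (divisor N).  Non-finite voxels (failed fits) are excluded.  With
    sigma = 0 the values are returned unchanged.
    """
    if not image.same_geometry(mask.volume):
        raise GeometryError("image and mask geometries differ")
    vals = image.data[mask.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("mask contains no finite image values")
    mu = vals.mean()
    sigma = vals.std()
    if sigma == 0.0:
        return vals
    return np.clip(vals, mu - n_sigma * sigma, mu + n_sigma * sigma)


def quantize(values, n_levels: int) -> np.ndarray:
    """Uniform quantization of values onto integer levels 1..n_levels.

    Equal-width bins over [min, max]; level = min(floor((x-min)/w)+1, n).
    A constant input maps to level 1 everywhere.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot quantize an empty value list")
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.shape, dtype=np.int64)
    w = (hi - lo) / n_levels
    return np.minimum(np.floor((v - lo) / w).astype(np.int64) + 1, n_levels)


def shape_features(mask: TumorMask, spacing=None) -> dict[str, float]:
    """Nine shape descriptors of the binary lesion mask (physical units).

    Surface area counts exposed voxel faces (overestimates smooth surfaces;
    deterministic and exactly testable).  Maximum diameter is the largest
    pairwise distance between mask voxel centers.  Minimum diameter is the
    smallest principal-axis extent, 2*sqrt(3*lambda_min) with lambda_min the
    smallest eigenvalue of the voxel-center covariance — the exact edge
    length for a uniform distribution along each principal axis.
    """
    data = mask.data
    if not data.any():
        raise ValueError("empty mask")
    sp = np.asarray(spacing if spacing is not None else mask.spacing,
                    dtype=float)
    n = int(data.sum())
    vox_vol = float(np.prod(sp))
    volume = n * vox_vol

    # exposed faces: for each axis, faces between a mask voxel and non-mask
    area = 0.0
    face = (sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1])
    for ax in range(3):
        pad = np.pad(data, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        diff = pad.astype(np.int8)
        exposed = np.abs(np.diff(diff, axis=ax)).sum()
        area += float(exposed) * face[ax]

    coords = np.argwhere(data) * sp                      # physical mm
    if n == 1:
        max_diam = 0.0
        min_diam = 0.0
    else:
        max_diam = _max_pairwise_distance(coords)
        cov = np.cov(coords, rowvar=False, bias=True)
        lam_min = max(float(np.linalg.eigvalsh(cov)[0]), 0.0)
        min_diam = 2.0 * np.sqrt(3.0 * lam_min)

    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    return {
        "n_voxels": float(n),
        "volume": volume,
        "surface_area": area,
        "surface_volume_ratio": area / volume,
        "max_diameter": max_diam,
        "min_diameter": min_diam,
        "compactness": volume / (np.sqrt(np.pi) * area ** 1.5),
        "spherical_disproportion": area / (4.0 * np.pi * r_eq ** 2),
        "sphericity": sphericity,
    }


def _max_pairwise_distance(coords: np.ndarray) -> float:
    """Largest pairwise distance, chunked to bound memory on big masks."""
    best = 0.0
    m = coords.shape[0]
    step = 2048
    for i in range(0, m, step):
        d = np.linalg.norm(coords[i:i + step, None, :] - coords[None, :, :],
                           axis=-1)
        best = max(best, float(d.max()))
    return best


def first_order_features(values, n_bins: int = 256) -> dict[str, float]:
    """Thirteen first-order statistics of the clipped masked intensities.

    energy = sum(x^2) on raw values; entropy (bits) and uniformity come from
    the n_bins-bin histogram probabilities; skewness and kurtosis are the
    standardized population central moments (kurtosis without the -3 excess
    correction) and are defined as 0 at zero variance.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("need at least one value")
    n = x.size
    mean = x.mean()
    var = x.var()                 # divisor N
    std = np.sqrt(var)
    energy = float((x ** 2).sum())
    if std > 0:
        skew = float(((x - mean) ** 3).mean() / std ** 3)
        kurt = float(((x - mean) ** 4).mean() / std ** 4)
    else:
        skew = 0.0
        kurt = 0.0
    hist, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max())) \
        if x.min() < x.max() else (np.array([n]), None)
    p = hist[hist > 0] / n
    return {
        "energy": energy,
        "entropy": float(-(p * np.log2(p)).sum()),
        "kurtosis": kurt,
        "max": float(x.max()),
        "mean": float(mean),
        "mad": float(np.abs(x - mean).mean()),
        "median": float(np.median(x)),
        "min": float(x.min()),
        "rms": float(np.sqrt(energy / n)),
        "skewness": skew,
        "std": float(std),
        "uniformity": float((p ** 2).sum()),
        "variance": float(var),
    }


def glcm_matrix(levels: np.ndarray, mask: TumorMask,
                n_levels: int | None = None) -> np.ndarray:
    """Direction-merged symmetric gray-level cooccurrence matrix.

    ``levels`` is an integer volume (levels 1..n_levels on mask voxels).
    All 26 neighbor directions at distance 1 are accumulated into a single
    matrix, symmetrized and normalized to sum 1.
    """
    lev = np.asarray(levels)
    m = mask.data
    if lev.shape != m.shape:
        raise GeometryError("levels volume and mask shapes differ")
    if n_levels is None:
        n_levels = int(lev[m].max())
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for dx, dy, dz in _DIRECTIONS:
        src = _shift_slice((dx, dy, dz), lev.shape)
        dst = _shift_slice((-dx, -dy, -dz), lev.shape)
        both = m[src] & m[dst]
        if not both.any():
            continue
        a = lev[src][both] - 1
        b = lev[dst][both] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise DegenerateMatrixError("mask admits no neighboring voxel pairs")
    return counts / total


def _shift_slice(offset, shape):
    out = []
    for d, s in zip(offset, shape):
        if d > 0:
            out.append(slice(0, s - d))
        elif d < 0:
            out.append(slice(-d, s))
        else:
            out.append(slice(0, s))
    return tuple(out)


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Nine Haralick-style statistics of a normalized cooccurrence matrix.

    Indices i, j run 1..n.  Correlation at zero marginal variance is defined
    as 1 (a perfectly ordered degenerate texture).
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < 0) or not np.isclose(P.sum(), 1.0):
        raise ValueError("P must be non-negative and sum to 1")
    n = P.shape[0]
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_i = float((i[:, 0] * px).sum())
    mu_j = float((j[0, :] * py).sum())
    sig_i = np.sqrt(float(((i[:, 0] - mu_i) ** 2 * px).sum()))
    sig_j = np.sqrt(float(((j[0, :] - mu_j) ** 2 * py).sum()))
    nz = P > 0
    if sig_i * sig_j > 0:
        corr = float(((i - mu_i) * (j - mu_j) * P).sum() / (sig_i * sig_j))
    else:
        corr = 1.0
    # sum-average over the diagonal-sum marginal p_{x+y}(k), k = 2..2n
    k = np.arange(2, 2 * n + 1)
    pxy = np.array([P[(i + j) == kk].sum() for kk in k])
    mu = 0.5 * (mu_i + mu_j)
    return {
        "glcm_energy": float((P ** 2).sum()),
        "glcm_contrast": float(((i - j) ** 2 * P).sum()),
        "glcm_entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "glcm_homogeneity": float((P / (1.0 + np.abs(i - j))).sum()),
        "glcm_correlation": corr,
        "glcm_sum_average": float((k * pxy).sum()),
        "glcm_variance": float(((i - mu) ** 2 * P).sum()),
        "glcm_dissimilarity": float((np.abs(i - j) * P).sum()),
        "glcm_autocorrelation": float((i * j * P).sum()),
    }


def extract_all(images: dict[str, ImageVolume],
                masks: dict[str, TumorMask] | TumorMask,
                shape_mask: TumorMask | None = None,
                n_bins: int = 256, n_levels: int = 32,
                n_sigma: float = 3.0) -> dict[str, float]:
    """Full per-lesion feature vector.

    ``images`` maps image name (subset of IMAGE_NAMES) to its volume;
    ``masks`` is either one mask shared by all images or a dict with a
    geometry-matched mask per image (native-space extraction).  Shape
    features come from ``shape_mask`` (default: the mask paired with the
    first available dynamic-space image).  With all 7 images this yields
    exactly 163 features.
    """
    if isinstance(masks, TumorMask):
        masks = {name: masks for name in images}
    for name in images:
        if name not in masks:
            raise ValueError(f"no mask supplied for image {name!r}")
        if not images[name].same_geometry(masks[name].volume):
            raise GeometryError(f"geometry mismatch for image {name!r}")
    if shape_mask is None:
        for name in IMAGE_NAMES:
            if name in masks and name not in ("tirm", "postc"):
                shape_mask = masks[name]
                break
        else:
            shape_mask = next(iter(masks.values()))

    out: dict[str, float] = {}
    for fname, val in shape_features(shape_mask).items():
        out[f"shape__{fname}"] = val
    for name in IMAGE_NAMES:
        if name not in images:
            continue
        vals = normalize_intensities(images[name], masks[name], n_sigma)
        for fname, v in first_order_features(vals, n_bins).items():
            out[f"{name}__{fname}"] = v
        lev_vol = np.zeros(images[name].shape, dtype=np.int64)
        finite = np.isfinite(images[name].data)
        mdata = masks[name].data & finite
        clip_vol = np.zeros(images[name].shape)
        clip_vol[mdata] = _clip_like(images[name].data[mdata], n_sigma)
        lev_vol[mdata] = quantize(clip_vol[mdata], n_levels)
        glcm_mask = TumorMask.from_array(mdata.astype(float),
                                         masks[name].volume.spacing,
                                         masks[name].volume.origin)
        P = glcm_matrix(lev_vol, glcm_mask, n_levels)
        for fname, v in glcm_features(P).items():
            out[f"{name}__{fname}"] = v
    return out


def _clip_like(vals: np.ndarray, n_sigma: float) -> np.ndarray:
    mu = vals.mean()
    sigma = vals.std()
    if sigma == 0.0:
        return vals
    return np.clip(vals, mu - n_sigma * sigma, mu + n_sigma * sigma)
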