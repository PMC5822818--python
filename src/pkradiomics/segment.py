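"""Semi-automatic lesion segmentation from the dynamic series.

Voxels inside a user-drawn bounding box whose relative signal enhancement
over the first time point exceeds a threshold (default 75%) are selected as
tumor, then reduced to the largest 26-connected component.  A nearest-
neighbor resampler maps the mask onto auxiliary image grids (axis-aligned
geometries only) so features can be extracted in each acquisition's native
space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume import DynamicSeries, GeometryError, ImageVolume

__all__ = ["TumorMask", "EmptySegmentationError", "relative_enhancement",
           "segment_lesion", "keep_largest_component", "resample_mask"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationError(ValueError):
    """No voxel survives segmentation/resampling."""


@dataclass(frozen=True)
class TumorMask:
    """Binary lesion mask with provenance (threshold and bounding box used)."""

    volume: ImageVolume
    threshold: float | None = None
    bbox: tuple | None = None

    def __post_init__(self):
        data = self.volume.data
        if not np.isin(data, (0.0, 1.0)).all():
            raise ValueError("mask values must be 0 or 1")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.volume.data.sum())

    @property
    def spacing(self):
        return self.volume.spacing

    @classmethod
    def from_array(cls, arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                   **prov) -> "TumorMask":
        vol = ImageVolume(np.asarray(arr, dtype=float), spacing, origin)
        return cls(volume=vol, **prov)


def relative_enhancement(series: DynamicSeries, mode: str = "max") -> ImageVolume:
    """Relative enhancement map over the first time point.

    RE(v) = (S_peak(v) - S(v, t1)) / S(v, t1), where the peak is the maximum
    over all post-baseline phases (``mode="max"``) or the first post-baseline
    phase (``mode="first"``).  Voxels with non-positive baseline are NaN.
    """
    if series.n_phases < 2:
        raise ValueError("relative enhancement needs at least 2 phases")
    if mode not in ("max", "first"):
        raise ValueError(f"unknown mode {mode!r}")
    base = series.frames[..., 0]
    post = series.frames[..., 1:]
    peak = post.max(axis=-1) if mode == "max" else post[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        re = (peak - base) / base
    re = np.where(base > 0, re, np.nan)
    return ImageVolume(re, series.spacing, series.origin)


def segment_lesion(series: DynamicSeries, bbox, threshold: float = 0.75,
                   mode: str = "max") -> TumorMask:
    """Threshold the enhancement map inside a bounding box and clean up.

    ``bbox`` is (x0, y0, z0, x1, y1, z1) in voxel indices, upper corners
    exclusive.  The relative-enhancement threshold is strict (RE > t).
    """
    shape = series.grid_shape
    x0, y0, z0, x1, y1, z1 = bbox
    if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
            and 0 <= z0 < z1 <= shape[2]):
        raise ValueError(f"bbox {bbox} not inside grid {shape}")
    re = relative_enhancement(series, mode=mode).data
    sel = np.zeros(shape, dtype=bool)
    box = re[x0:x1, y0:y1, z0:z1]
    sel[x0:x1, y0:y1, z0:z1] = np.isfinite(box) & (box > threshold)
    if not sel.any():
        raise EmptySegmentationError(
            f"no voxel exceeds enhancement threshold {threshold}")
    mask = TumorMask.from_array(sel, series.spacing, series.origin,
                                threshold=threshold, bbox=tuple(bbox))
    return keep_largest_component(mask)


def keep_largest_component(mask: TumorMask, connectivity: int = 26) -> TumorMask:
    """Retain only the largest 26-connected component.

    Ties are broken in favor of the component containing the lowest linear
    voxel index.  Idempotent.
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported")
    data = mask.data
    if not data.any():
        raise EmptySegmentationError("empty mask")
    labeled, n = ndimage.label(data, structure=_STRUCT_26)
    if n == 1:
        return mask
    sizes = np.bincount(labeled.ravel())[1:]          # skip background
    best = sizes.max()
    tied = np.nonzero(sizes == best)[0] + 1
    if tied.size == 1:
        keep = tied[0]
    else:
        flat = labeled.ravel()
        first_idx = {lab: np.argmax(flat == lab) for lab in tied}
        keep = min(tied, key=lambda lab: first_idx[lab])
    return replace(mask, volume=mask.volume.with_data(
        (labeled == keep).astype(float)))


def resample_mask(mask: TumorMask, target: ImageVolume) -> TumorMask:
    """Nearest-neighbor resampling of the mask onto a target geometry.

    Works in physical coordinates assuming axis-aligned grids (origin +
    spacing).  Target voxels whose centers fall outside the source grid are
    background.  Raises EmptySegmentationError if nothing maps inside.
    """
    src = mask.volume
    if src.same_geometry(target):
        return mask
    idx = []
    inside = []
    for a in range(3):
        centers = target.origin[a] + target.spacing[a] * np.arange(target.shape[a])
        i = np.rint((centers - src.origin[a]) / src.spacing[a]).astype(int)
        inside.append((i >= 0) & (i < src.shape[a]))
        idx.append(np.clip(i, 0, src.shape[a] - 1))
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    ok = np.logical_and.reduce(np.meshgrid(*inside, indexing="ij"))
    out = np.zeros(target.shape, dtype=bool)
    out[ok] = mask.data[ii[ok], jj[ok], kk[ok]]
    if not out.any():
        raise EmptySegmentationError("mask is empty after resampling to "
                                     f"grid {target.shape}")
    return TumorMask(volume=ImageVolume(out.astype(float), target.spacing,
                                        target.origin),
                     threshold=mask.threshold, bbox=mask.bbox)
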