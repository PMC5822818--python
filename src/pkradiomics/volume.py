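"""Image containers and NIfTI-1 I/O.

All volumes in this package are axis-aligned scalar grids: data plus voxel
spacing (mm) and a physical origin (mm).  Oblique orientations are rejected
on read — the simulator produces axis-aligned grids and the geometry model
keeps resampling exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "DynamicSeries", "read_volume", "write_volume",
           "read_series", "write_series", "GeometryError"]


class GeometryError(ValueError):
    """Raised when volume geometries are incompatible or unsupported."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with voxel spacing and origin (both in mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise GeometryError(f"expected 3D data, got shape {arr.shape}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same geometry, new voxel values."""
        return replace(self, data=data)

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis (mm)."""
        return tuple(self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                     for a in range(3))


@dataclass(frozen=True)
class DynamicSeries:
    """A 4D dynamic stack: ``frames[..., t]`` with acquisition time per phase (s)."""

    frames: np.ndarray                       # (nx, ny, nz, n_phases)
    times: np.ndarray                        # seconds, strictly increasing
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.float64)
        times = np.asarray(self.times, dtype=np.float64)
        if frames.ndim != 4:
            raise GeometryError(f"expected 4D frames, got shape {frames.shape}")
        if times.ndim != 1 or times.size != frames.shape[3]:
            raise ValueError("times must be 1D with one entry per phase")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("phase times must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_phases(self) -> int:
        return self.frames.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[:3]

    def phase(self, t: int) -> ImageVolume:
        return ImageVolume(self.frames[..., t], self.spacing, self.origin)

    def geometry_volume(self) -> ImageVolume:
        """A zero-filled volume carrying this series' 3D geometry."""
        return ImageVolume(np.zeros(self.grid_shape), self.spacing, self.origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _check_axis_aligned(affine: np.ndarray, path) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if not np.allclose(off_diag, 0.0, atol=1e-4):
        raise GeometryError(f"{path}: oblique orientation not supported "
                            "(rotation matrix must be diagonal)")
    diag = np.diag(rot)
    if np.any(diag == 0):
        raise GeometryError(f"{path}: degenerate affine")
    # fold negative axis scales into spacing magnitude; keep origin as stored
    return tuple(float(abs(d)) for d in diag), tuple(float(o) for o in affine[:3, 3])


def read_volume(path) -> ImageVolume:
    """Read a 3D NIfTI-1 volume (axis-aligned affines only)."""
    img = nib.load(str(path))
    spacing, origin = _check_axis_aligned(img.affine, path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ImageVolume(data, spacing, origin)


def write_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_series(path, times) -> DynamicSeries:
    """Read a 4D NIfTI-1 dynamic series; phase times come from config (s)."""
    img = nib.load(str(path))
    spacing, origin = _check_axis_aligned(img.affine, path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise GeometryError(f"{path}: expected a 4D series, got shape {data.shape}")
    return DynamicSeries(data, np.asarray(times, dtype=np.float64), spacing, origin)


def write_series(series: DynamicSeries, path) -> None:
    img = nib.Nifti1Image(np.asarray(series.frames, dtype=np.float64),
                          _affine(series.spacing, series.origin))
    nib.save(img, str(path))
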