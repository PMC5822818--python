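"""Pharmacokinetic mapping: R1/M0 from variable-flip-angle SPGR signals,
voxelwise Tofts parameters (ktrans, kep, ve) and the initial area under the
concentration curve (iAUC) from a dynamic contrast-enhanced series.

Signal-to-concentration uses the full SPGR inversion (not the linearized
small-enhancement approximation), so noiseless forward-simulated phantoms
round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .aif import AIFModel, generate_aif
from .kinetics import spgr_invert_r1, tissue_concentration
from .volume import DynamicSeries, GeometryError, ImageVolume

__all__ = ["PKMaps", "fit_vfa_r1", "signal_to_concentration", "fit_tofts",
           "compute_iauc", "compute_pk_maps",
           "KTRANS_BOUNDS", "KEP_BOUNDS", "DEFAULT_R1_RELAXIVITY"]

KTRANS_BOUNDS = (0.0, 5.0)       # 1/min
KEP_BOUNDS = (1e-3, 10.0)        # 1/min
DEFAULT_R1_RELAXIVITY = 4.5      # 1/mM/s, gadolinium contrast agent at 3T


@dataclass(frozen=True)
class PKMaps:
    """Bundle of pharmacokinetic maps sharing one geometry.

    ktrans and kep are in 1/min, ve dimensionless, iauc in mM*s, r1 in 1/s.
    Voxels outside the fitted region (or failed fits) are NaN.
    """

    ktrans: ImageVolume
    kep: ImageVolume
    ve: ImageVolume
    iauc: ImageVolume
    r1: ImageVolume

    def __post_init__(self):
        ref = self.ktrans
        for name in ("kep", "ve", "iauc", "r1"):
            if not getattr(self, name).same_geometry(ref):
                raise GeometryError(f"{name} map geometry differs from ktrans")

    def as_dict(self) -> dict[str, ImageVolume]:
        return {"ktrans": self.ktrans, "kep": self.kep, "ve": self.ve,
                "iauc": self.iauc, "r1": self.r1}


def fit_vfa_r1(signals, flip_angles, TR: float):
    """Linearized DESPOT1 fit of the variable-flip-angle SPGR signal.

    Regresses S/sin(a) on S/tan(a) across flip angles: the slope is
    E1 = exp(-TR*R1) and the intercept M0*(1-E1).  ``signals`` may be a 1D
    per-voxel vector or an array (..., n_fa); returns (R1 [1/ms], M0, valid).
    Voxels whose slope falls outside (0, 1) are flagged invalid (NaN).
    """
    s = np.asarray(signals, dtype=np.float64)
    fa = np.asarray(flip_angles, dtype=np.float64)
    if fa.ndim != 1 or np.unique(fa).size < 2:
        raise ValueError("need at least 2 distinct flip angles")
    if s.shape[-1] != fa.size:
        raise ValueError("last axis of signals must match flip_angles")
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")

    alpha = np.deg2rad(fa)
    y = s / np.sin(alpha)
    x = s / np.tan(alpha)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=-1)
    sxy = ((x - xm) * (y - ym)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = ym[..., 0] - slope * xm[..., 0]

    valid = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
    slope_safe = np.where(valid, slope, 0.5)
    r1 = np.where(valid, -np.log(slope_safe) / TR, np.nan)
    m0 = np.where(valid, intercept / (1.0 - slope_safe), np.nan)
    if s.ndim == 1:
        return float(r1), float(m0), bool(valid)
    return r1, m0, valid


def signal_to_concentration(series_voxel, R1_0: float, M0: float, TR: float,
                            flip_angle: float,
                            r1_relaxivity: float = DEFAULT_R1_RELAXIVITY,
                            baseline_index: int = 0):
    """Convert an SPGR signal curve to tissue concentration Ct(t) in mM.

    Per phase the SPGR equation is inverted for R1(t) given M0 and the flip
    angle; Ct(t) = (R1(t) - R1_0) / r1 with units reconciled (R1 in 1/ms,
    relaxivity in 1/mM/s).  The curve is referenced to its baseline phase so
    baseline Ct is zero by construction.  ``series_voxel`` may be 1D
    (n_phases,) or (..., n_phases).  Returns (ct, clamped_mask).
    """
    s = np.asarray(series_voxel, dtype=np.float64)
    if not np.isfinite(R1_0) or R1_0 <= 0:
        raise ValueError("R1_0 must be positive and finite")
    r1_t, clamped = spgr_invert_r1(s, M0, TR, flip_angle)     # 1/ms
    ct = (r1_t - R1_0) * 1000.0 / r1_relaxivity               # mM
    ct = ct - ct[..., baseline_index][..., None]
    return ct, clamped


def _profiled_rss(kep: float, ct: np.ndarray, cp: np.ndarray, times) -> tuple[float, float]:
    """Residual sum of squares at kep with ktrans profiled out (linear LSQ)."""
    f = tissue_concentration(1.0, kep, cp, times)
    den = float(f @ f)
    if den == 0.0:
        return float(ct @ ct), 0.0
    kt = float(np.clip((ct @ f) / den, *KTRANS_BOUNDS))
    resid = ct - kt * f
    return float(resid @ resid), kt


def fit_tofts(ct, aif_curve, times, n_starts: int = 3):
    """Nonlinear least-squares Tofts fit of a single concentration curve.

    The model Ct(t) = ktrans * (Cp (*) exp(-kep t)) is linear in ktrans, so
    ktrans is profiled out and kep is optimized by bounded scalar search over
    KEP_BOUNDS, restarted on ``n_starts`` subintervals for robustness.
    Returns {"ktrans", "kep", "ve"} (1/min, 1/min, dimensionless).
    """
    ct = np.asarray(ct, dtype=np.float64)
    cp = np.asarray(aif_curve, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    if ct.shape != t.shape or cp.shape != t.shape:
        raise ValueError("ct, aif_curve and times must share one grid")
    if t.size < 10:
        raise ValueError("need at least 10 time points for a Tofts fit")
    if not np.any(ct != 0.0):
        return {"ktrans": 0.0, "kep": np.nan, "ve": 0.0}

    lo, hi = np.log(KEP_BOUNDS[0]), np.log(KEP_BOUNDS[1])
    edges = np.linspace(lo, hi, n_starts + 1)
    best = None
    for i in range(n_starts):
        res = minimize_scalar(
            lambda lk: _profiled_rss(np.exp(lk), ct, cp, t)[0],
            bounds=(edges[i], edges[i + 1]), method="bounded",
            options={"xatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    kep = float(np.exp(best.x))
    rss, ktrans = _profiled_rss(kep, ct, cp, t)
    if not np.isfinite(rss):
        return {"ktrans": np.nan, "kep": np.nan, "ve": np.nan}
    return {"ktrans": ktrans, "kep": kep, "ve": ktrans / kep}


def compute_iauc(ct, times, window_s: float = 60.0, onset_s: float = 0.0):
    """Initial area under the concentration curve (mM*s) by trapezoid.

    Integrates Ct from ``onset_s`` to ``onset_s + window_s`` with linear
    interpolation at the window edges; a window extending past the last
    phase is truncated there (with a warning).  ``ct`` may be 1D or
    (..., n_phases) for vectorized map computation.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = np.asarray(times, dtype=np.float64)
    ct = np.asarray(ct, dtype=np.float64)
    t_end = onset_s + window_s
    if t_end > t[-1]:
        warnings.warn("iAUC window extends past the last phase; truncated",
                      stacklevel=2)
        t_end = t[-1]
    if onset_s >= t[-1]:
        return np.zeros(ct.shape[:-1]) if ct.ndim > 1 else 0.0

    # augmented grid with exact window edges
    inner = t[(t > onset_s) & (t < t_end)]
    grid = np.concatenate(([onset_s], inner, [t_end]))
    vals = np.stack([_interp_along_last(g, t, ct) for g in grid], axis=-1) \
        if ct.ndim > 1 else np.interp(grid, t, ct)
    out = np.trapezoid(vals, grid, axis=-1)
    return out if ct.ndim > 1 else float(out)


def _interp_along_last(x: float, t: np.ndarray, ct: np.ndarray) -> np.ndarray:
    """Linear interpolation of (..., T) curves at a scalar time."""
    idx = np.searchsorted(t, x)
    if idx == 0:
        return ct[..., 0]
    if idx >= t.size:
        return ct[..., -1]
    t0, t1 = t[idx - 1], t[idx]
    if x == t1:
        return ct[..., idx]
    w = (x - t0) / (t1 - t0)
    return (1 - w) * ct[..., idx - 1] + w * ct[..., idx]


def _fit_tofts_grid(ct_mat: np.ndarray, cp: np.ndarray, times,
                    n_grid: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Tofts fit of many curves: kep grid search + local refine.

    ct_mat is (V, T).  A log-spaced kep grid basis is shared across voxels;
    the per-voxel optimum is refined by parabolic interpolation of the
    residual in log(kep) and ktrans re-profiled at the refined kep.
    """
    kep_grid = np.exp(np.linspace(np.log(KEP_BOUNDS[0]), np.log(KEP_BOUNDS[1]),
                                  n_grid))
    F = tissue_concentration(1.0, kep_grid, cp, times)        # (K, T)
    den = (F * F).sum(axis=1)                                  # (K,)
    num = ct_mat @ F.T                                         # (V, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.clip(num / den, *KTRANS_BOUNDS)
    ss_ct = (ct_mat ** 2).sum(axis=1)[:, None]
    rss = ss_ct - 2.0 * kt * num + kt ** 2 * den               # (V, K)
    best = np.argmin(rss, axis=1)

    # parabolic refinement in log(kep) around the grid optimum
    logk = np.log(kep_grid)
    b = np.clip(best, 1, n_grid - 2)
    r0 = rss[np.arange(len(b)), b - 1]
    r1_ = rss[np.arange(len(b)), b]
    r2 = rss[np.arange(len(b)), b + 1]
    denom = (r0 - 2 * r1_ + r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (r0 - r2) / denom
    shift = np.where(np.isfinite(shift), np.clip(shift, -1.0, 1.0), 0.0)
    dlog = logk[1] - logk[0]
    kep = np.exp(logk[b] + shift * dlog)
    kep = np.clip(kep, *KEP_BOUNDS)

    f_ref = tissue_concentration(1.0, kep, cp, times)          # (V, T)
    den_ref = (f_ref * f_ref).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ktrans = np.clip((ct_mat * f_ref).sum(axis=1) / den_ref, *KTRANS_BOUNDS)
    flat = ss_ct[:, 0] == 0.0
    ktrans[flat] = 0.0
    kep[flat] = np.nan
    return ktrans, kep


def compute_pk_maps(series: DynamicSeries, vfa_volumes: dict[float, ImageVolume],
                    aif: AIFModel, roi=None, TR: float = 5.3,
                    r1_relaxivity: float = DEFAULT_R1_RELAXIVITY,
                    iauc_window_s: float = 60.0, onset_s: float | None = None,
                    baseline_index: int = 0, dynamic_flip_angle: float = 20.0,
                    n_kep_grid: int = 256) -> PKMaps:
    """Voxelwise pharmacokinetic mapping inside a region of interest.

    ``vfa_volumes`` maps flip angle (degrees) to its SPGR volume; geometry
    must match the dynamic series.  ``roi`` is a voxel-index bounding box
    (x0, y0, z0, x1, y1, z1) with exclusive upper corners, or None for the
    whole grid.  ``onset_s`` defaults to the second phase time (injection at
    the end of the first phase).  Voxels outside the roi, or with invalid
    R1 fits, are NaN in every map.
    """
    geom = series.geometry_volume()
    fas = sorted(vfa_volumes)
    for fa in fas:
        if not vfa_volumes[fa].same_geometry(geom):
            raise GeometryError(f"VFA volume at {fa} deg does not match the "
                                "dynamic series geometry")
    shape = series.grid_shape
    if roi is None:
        roi = (0, 0, 0, *shape)
    x0, y0, z0, x1, y1, z1 = roi
    if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
            and 0 <= z0 < z1 <= shape[2]):
        raise ValueError(f"roi {roi} not inside grid {shape}")
    if onset_s is None:
        onset_s = float(series.times[1]) if series.n_phases > 1 else 0.0

    sl = (slice(x0, x1), slice(y0, y1), slice(z0, z1))
    vfa_stack = np.stack([vfa_volumes[fa].data[sl] for fa in fas], axis=-1)
    r1_ms, m0, valid = fit_vfa_r1(vfa_stack, fas, TR)

    dyn = series.frames[sl]                                    # (vx,vy,vz,T)
    roi_shape = dyn.shape[:3]
    nvox = int(np.prod(roi_shape))
    ct = np.full((nvox, series.n_phases), np.nan)
    v = valid.reshape(nvox)
    dyn_flat = dyn.reshape(nvox, series.n_phases)
    r1_flat = r1_ms.reshape(nvox)
    m0_flat = m0.reshape(nvox)
    if v.any():
        # bulk SPGR inversion with per-voxel M0 and baseline referencing
        alpha = np.deg2rad(dynamic_flip_angle)
        a = dyn_flat[v] / (m0_flat[v, None] * np.sin(alpha))
        with np.errstate(divide="ignore", invalid="ignore"):
            e1 = (1.0 - a) / (1.0 - a * np.cos(alpha))
        e1 = np.clip(np.nan_to_num(e1, nan=1.0 - 1e-12), 1e-12, 1.0 - 1e-12)
        r1_t = -np.log(e1) / TR
        ct_v = (r1_t - r1_flat[v, None]) * 1000.0 / r1_relaxivity
        ct[v] = ct_v - ct_v[:, baseline_index][:, None]

    cp = generate_aif(aif, series.times)
    ktrans = np.full(nvox, np.nan)
    kep = np.full(nvox, np.nan)
    if v.any():
        ktrans[v], kep[v] = _fit_tofts_grid(ct[v], cp, series.times, n_kep_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.clip(ktrans / kep, 0.0, 1.0)
    iauc = np.full(nvox, np.nan)
    if v.any():
        iauc[v] = compute_iauc(ct[v], series.times, iauc_window_s, onset_s)

    def to_map(flat: np.ndarray) -> ImageVolume:
        full = np.full(shape, np.nan)
        full[sl] = flat.reshape(roi_shape)
        return geom.with_data(full)

    r1_s = np.where(v, r1_flat * 1000.0, np.nan)               # 1/ms -> 1/s
    return PKMaps(ktrans=to_map(ktrans), kep=to_map(kep), ve=to_map(ve),
                  iauc=to_map(iauc), r1=to_map(r1_s))
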