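"""Forward physics shared by the simulator and the fitting stages.

Two closed-form models:

* the standard (one-compartment) Tofts model,
      Ct(t) = ktrans * int_0^t Cp(tau) exp(-kep (t - tau)) dtau,
  evaluated by exact recursive discretization assuming Cp piecewise linear
  between grid points — stable and consistent with the sampling grid;

* the spoiled gradient-echo (SPGR/VIBE) steady-state signal,
      S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),  E1 = exp(-TR * R1),
  with TR in ms and R1 in 1/ms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tissue_concentration", "spgr_signal", "spgr_invert_r1"]


def tissue_concentration(ktrans: float, kep, cp: np.ndarray, times) -> np.ndarray:
    """Tofts tissue concentration on the AIF's own time grid.

    ktrans and kep are in 1/min; times in seconds; cp in mM.  ``kep`` may be
    a scalar or a 1D array of K values, in which case the result has shape
    (K, len(times)) — the per-kep convolution basis used by map fitting.

    Exact for piecewise-linear Cp: with dt the step and E = exp(-kep dt),

        Ct[i+1] = Ct[i] E + ktrans (c_i (1-E)/kep + s_i (dt/kep - (1-E)/kep^2))

    where c_i = Cp[t_i], s_i the slope of Cp on the interval.
    """
    t = np.asarray(times, dtype=np.float64) / 60.0     # minutes
    cp = np.asarray(cp, dtype=np.float64)
    if cp.shape != t.shape:
        raise ValueError("cp and times must have the same length")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    kep_arr = np.atleast_1d(np.asarray(kep, dtype=np.float64))
    if np.any(kep_arr <= 0):
        raise ValueError("kep must be positive")

    n = t.size
    ct = np.zeros((kep_arr.size, n))
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        c0 = cp[i]
        slope = (cp[i + 1] - cp[i]) / dt
        e = np.exp(-kep_arr * dt)
        seg = c0 * (1.0 - e) / kep_arr + slope * (dt / kep_arr - (1.0 - e) / kep_arr ** 2)
        ct[:, i + 1] = ct[:, i] * e + ktrans * seg
    if np.isscalar(kep) or np.ndim(kep) == 0:
        return ct[0]
    return ct


def spgr_signal(R1, M0, TR: float, flip_angle):
    """SPGR steady-state signal; R1 in 1/ms, TR in ms, flip angle in degrees."""
    R1 = np.asarray(R1, dtype=np.float64)
    if np.any(R1 <= 0):
        raise ValueError("R1 must be positive")
    alpha = np.deg2rad(np.asarray(flip_angle, dtype=np.float64))
    if np.any(alpha <= 0) or np.any(alpha >= np.pi / 2):
        raise ValueError("flip angle must lie in (0, 90) degrees")
    e1 = np.exp(-TR * R1)
    return M0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def spgr_invert_r1(signal, M0, TR: float, flip_angle):
    """Invert the SPGR equation for R1 (1/ms) given M0 and the flip angle.

    Signals implying E1 outside (0, 1) are clamped into the open interval;
    a boolean ``clamped`` mask is returned alongside R1.
    """
    s = np.asarray(signal, dtype=np.float64)
    alpha = float(np.deg2rad(flip_angle))
    a = s / (M0 * np.sin(alpha))
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - a) / (1.0 - a * np.cos(alpha))
    eps = 1e-12
    clamped = ~np.isfinite(e1) | (e1 <= 0.0) | (e1 >= 1.0)
    e1 = np.clip(np.nan_to_num(e1, nan=1.0 - eps), eps, 1.0 - eps)
    r1 = -np.log(e1) / TR
    return r1, clamped
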