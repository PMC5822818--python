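"""Arterial input functions (AIF).

The default is the classic biexponential population AIF

    Cp(t) = D * (a1 * exp(-m1*t) + a2 * exp(-m2*t)),   t >= onset,

with amplitudes in mM*kg/L, decay rates in 1/min and dose D in mmol/kg, so
Cp is a plasma concentration in mM.  The constants below are the standard
population values (a1 = 3.99, a2 = 4.78 mM*kg/L; m1 = 0.144, m2 = 0.0111
/min) at the clinical dose of 0.1 mmol/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AIFModel", "generate_aif", "POPULATION_BIEXPONENTIAL"]


@dataclass(frozen=True)
class AIFModel:
    """Plasma contrast concentration model Cp(t).

    model_id is one of ``"biexponential"``, ``"constant"`` or ``"custom"``.
    For the constant model, ``level`` is the plateau concentration in mM.
    For the custom model, ``samples`` are concentrations on ``sample_times``
    (seconds) and are linearly interpolated.
    ``onset_time`` is the contrast-arrival time in seconds; Cp = 0 before it.
    """

    model_id: str = "biexponential"
    dose: float = 0.1                 # mmol/kg
    a1: float = 3.99                  # mM*kg/L
    a2: float = 4.78                  # mM*kg/L
    m1: float = 0.144                 # 1/min
    m2: float = 0.0111                # 1/min
    onset_time: float = 0.0           # s
    level: float = 1.0                # mM (constant model)
    sample_times: np.ndarray | None = None   # s (custom model)
    samples: np.ndarray | None = None        # mM (custom model)

    def __post_init__(self):
        if self.model_id not in ("biexponential", "constant", "custom"):
            raise ValueError(f"unknown AIF model {self.model_id!r}")
        if self.model_id == "biexponential" and (self.m1 <= 0 or self.m2 <= 0):
            raise ValueError("decay rates must be positive")
        if self.model_id == "custom":
            if self.sample_times is None or self.samples is None:
                raise ValueError("custom AIF requires sample_times and samples")
            st = np.asarray(self.sample_times, dtype=np.float64)
            sv = np.asarray(self.samples, dtype=np.float64)
            if st.ndim != 1 or st.shape != sv.shape:
                raise ValueError("sample_times and samples must be equal-length 1D")
            if st.size >= 2 and not np.all(np.diff(st) > 0):
                raise ValueError("sample_times must be strictly increasing")
            if np.any(sv < 0):
                raise ValueError("AIF samples must be non-negative")
            object.__setattr__(self, "sample_times", st)
            object.__setattr__(self, "samples", sv)


POPULATION_BIEXPONENTIAL = AIFModel()


def generate_aif(model: AIFModel, times) -> np.ndarray:
    """Sample Cp(t) in mM on a strictly increasing time grid (seconds)."""
    t = np.asarray(times, dtype=np.float64)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1D array")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    tau_min = (t - model.onset_time) / 60.0     # minutes since arrival
    active = tau_min >= 0
    cp = np.zeros_like(t)
    if model.model_id == "constant":
        cp[active] = model.level
    elif model.model_id == "biexponential":
        tm = tau_min[active]
        cp[active] = model.dose * (model.a1 * np.exp(-model.m1 * tm)
                                   + model.a2 * np.exp(-model.m2 * tm))
    else:  # custom, sample_times measured from onset
        tm = tau_min[active] * 60.0
        cp[active] = np.interp(tm, model.sample_times, model.samples)
    return np.maximum(cp, 0.0)
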