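"""Physics-based DCE-MRI phantoms and labeled synthetic cohorts.

A phantom is a spherical lesion on a homogeneous background.  Its dynamic
signal is generated by the forward chain actually inverted downstream:
Tofts tissue concentration driven by a population AIF, converted to
longitudinal relaxation via R1(t) = R1(0) + r1 * Ct(t), and passed through
the SPGR steady-state equation at the dynamic flip angle.  Variable-flip-
angle volumes use the baseline R1.  Acquisition defaults mirror a 3T
breast protocol: 60 dynamic phases at 9 s/phase, flip angles
2/5/8/12/15/20 degrees, TR = 5.3 ms, injection at the end of phase 1.

Cohorts plant multiplicative effects on the pharmacokinetic parameters of
positive-class lesions so that downstream feature selection and modeling
have a known signal to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aif import AIFModel, generate_aif
from .kinetics import spgr_signal, tissue_concentration
from .pk import DEFAULT_R1_RELAXIVITY, PKMaps, compute_iauc
from .volume import DynamicSeries, ImageVolume

__all__ = ["PhantomSpec", "CohortSpec", "Phantom", "simulate_phantom",
           "generate_cohort", "DEFAULT_FLIP_ANGLES", "DEFAULT_TIMES"]

DEFAULT_FLIP_ANGLES = (2.0, 5.0, 8.0, 12.0, 15.0, 20.0)   # degrees
DEFAULT_TIMES = tuple(9.0 * i for i in range(60))          # s, 60 phases


def _default_times() -> np.ndarray:
    return np.asarray(DEFAULT_TIMES)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one spherical-lesion phantom.

    Units: spacing and lesion_radius mm; ktrans/kep 1/min; true_R1 1/s;
    M0 arbitrary signal units; noise_sd a fraction of the per-voxel
    baseline dynamic signal; times s; TR ms; flip angles degrees.
    ``param_jitter`` adds per-voxel lognormal heterogeneity (CV fraction)
    to the lesion's ktrans/kep.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    lesion_center: tuple[int, int, int] = (12, 12, 12)
    lesion_radius: float = 9.3
    true_ktrans: float = 0.25
    true_kep: float = 0.5
    background_ktrans: float = 0.0
    background_kep: float = 0.5
    true_R1: float = 1.0
    background_R1: float = 0.7
    M0: float = 1000.0
    noise_sd: float = 0.0
    param_jitter: float = 0.0
    times: np.ndarray = field(default_factory=_default_times)
    flip_angles: tuple[float, ...] = DEFAULT_FLIP_ANGLES
    dynamic_flip_angle: float = 20.0
    TR: float = 5.3
    r1_relaxivity: float = DEFAULT_R1_RELAXIVITY
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "times",
                           np.asarray(self.times, dtype=np.float64))
        if not (self.true_kep >= self.true_ktrans > 0):
            raise ValueError("need true_kep >= true_ktrans > 0 so that "
                             "ve = ktrans/kep lies in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        ctr = np.asarray(self.lesion_center, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        ext = np.asarray(self.grid_shape, dtype=float)
        if np.any((ctr * sp - self.lesion_radius) < -0.5 * sp) or \
           np.any((ctr * sp + self.lesion_radius) > (ext - 0.5) * sp):
            raise ValueError("lesion sphere does not fit inside the grid")

    @property
    def onset_s(self) -> float:
        """Contrast arrival: end of the first dynamic phase."""
        return float(self.times[1]) if self.times.size > 1 else 0.0


@dataclass(frozen=True)
class Phantom:
    """One simulated lesion: dynamic series, VFA set, truth maps and mask."""

    series: DynamicSeries
    vfa: dict[float, ImageVolume]
    truth: PKMaps
    mask: ImageVolume            # binary truth lesion mask, dynamic geometry
    tirm: ImageVolume            # fat-suppressed T2-weighted-like, coarser grid
    postc: ImageVolume           # delayed postcontrast-like, finer grid
    spec: PhantomSpec


def _sphere_mask(shape, spacing, origin, center_mm, radius) -> np.ndarray:
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = ((xx - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
          + (zz - center_mm[2]) ** 2)
    return d2 <= radius ** 2


def _aux_grid(spec: PhantomSpec, factor: float):
    """Auxiliary grid covering the same physical extent at scaled spacing."""
    sp = tuple(s * factor for s in spec.spacing)
    extent = [spec.grid_shape[a] * spec.spacing[a] for a in range(3)]
    shape = tuple(max(2, int(np.ceil(extent[a] / sp[a]))) for a in range(3))
    return shape, sp


def simulate_phantom(spec: PhantomSpec, aif: AIFModel | None = None) -> Phantom:
    """Run the forward model for one phantom (deterministic under its seed)."""
    rng = np.random.default_rng(spec.seed)
    if aif is None:
        aif = AIFModel(onset_time=spec.onset_s)
    cp = generate_aif(aif, spec.times)

    shape = spec.grid_shape
    center_mm = tuple(spec.lesion_center[a] * spec.spacing[a] for a in range(3))
    lesion = _sphere_mask(shape, spec.spacing, (0, 0, 0), center_mm,
                          spec.lesion_radius)

    ktrans_map = np.where(lesion, spec.true_ktrans, spec.background_ktrans)
    kep_map = np.where(lesion, spec.true_kep, spec.background_kep)
    if spec.param_jitter > 0:
        sig = np.sqrt(np.log1p(spec.param_jitter ** 2))
        jit_kt = np.exp(rng.normal(-0.5 * sig ** 2, sig, shape))
        jit_ke = np.exp(rng.normal(-0.5 * sig ** 2, sig, shape))
        ktrans_map = np.where(lesion, ktrans_map * jit_kt, ktrans_map)
        kep_map = np.where(lesion, np.maximum(kep_map * jit_ke, ktrans_map),
                           kep_map)
    r1_map = np.where(lesion, spec.true_R1, spec.background_R1)     # 1/s

    # tissue concentration per voxel; group identical (ktrans, kep) pairs
    n_t = spec.times.size
    ct = np.zeros(shape + (n_t,))
    flat_kt = ktrans_map.ravel()
    flat_ke = kep_map.ravel()
    pairs = np.stack([flat_kt, flat_ke], axis=1)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    curves = np.zeros((len(uniq), n_t))
    for i, (kt, ke) in enumerate(uniq):
        if kt > 0:
            curves[i] = tissue_concentration(kt, ke, cp, spec.times)
    ct = curves[inv].reshape(shape + (n_t,))

    # dynamic SPGR signal
    r1_t_ms = (r1_map[..., None] + spec.r1_relaxivity * ct) / 1000.0
    frames = spgr_signal(r1_t_ms, spec.M0, spec.TR, spec.dynamic_flip_angle)
    baseline = frames[..., 0]
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, 1.0, frames.shape) \
            * (spec.noise_sd * baseline)[..., None]
        frames = np.maximum(frames, 0.0)
    series = DynamicSeries(frames, spec.times, spec.spacing)

    # variable-flip-angle volumes at baseline R1
    vfa: dict[float, ImageVolume] = {}
    r1_base_ms = r1_map / 1000.0
    for fa in spec.flip_angles:
        vol = spgr_signal(r1_base_ms, spec.M0, spec.TR, fa)
        if spec.noise_sd > 0:
            vol = np.maximum(vol + rng.normal(0.0, 1.0, vol.shape)
                             * spec.noise_sd * vol, 0.0)
        vfa[float(fa)] = ImageVolume(vol, spec.spacing)

    # truth maps
    geom = series.geometry_volume()
    ve_map = np.where(kep_map > 0, ktrans_map / kep_map, 0.0)
    iauc_map = compute_iauc(ct.reshape(-1, n_t), spec.times, 60.0,
                            spec.onset_s).reshape(shape)
    truth = PKMaps(ktrans=geom.with_data(ktrans_map),
                   kep=geom.with_data(kep_map),
                   ve=geom.with_data(ve_map),
                   iauc=geom.with_data(iauc_map),
                   r1=geom.with_data(r1_map))
    mask = geom.with_data(lesion.astype(np.float64))

    # auxiliary contrasts on their native (coarser / finer) grids
    tirm = _make_aux(spec, center_mm, rng, factor=4.0 / 3.0,
                     background=100.0, lesion_value=100.0 + 160.0 * ve_map.max())
    late_ct = ct[..., -1]
    lesion_late = float(late_ct[lesion].mean()) if lesion.any() else 0.0
    postc = _make_aux(spec, center_mm, rng, factor=2.0 / 3.0,
                      background=150.0,
                      lesion_value=150.0 * (1.0 + 2.0 * lesion_late))
    return Phantom(series=series, vfa=vfa, truth=truth, mask=mask,
                   tirm=tirm, postc=postc, spec=spec)


def _make_aux(spec: PhantomSpec, center_mm, rng, factor: float,
              background: float, lesion_value: float) -> ImageVolume:
    shape, sp = _aux_grid(spec, factor)
    lesion = _sphere_mask(shape, sp, (0, 0, 0), center_mm, spec.lesion_radius)
    data = np.where(lesion, lesion_value, background).astype(np.float64)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd * background, shape)
    return ImageVolume(data, sp)


def _empty_effects() -> dict:
    return {"lesion_class": {"ktrans": 1.6}}


@dataclass(frozen=True)
class CohortSpec:
    """A labeled cohort of phantoms with planted parameter-outcome effects.

    ``effect_map`` maps task name -> {parameter: multiplier} applied to the
    positive class ("ktrans", "kep" and "R1" are recognized).  Between-
    lesion biological variability is lognormal with coefficient of
    variation ``param_cv`` around the template's true values.
    """

    n_lesions: int = 40
    class_balance: float = 0.5
    tasks: tuple[str, ...] = ("lesion_class",)
    effect_map: dict = field(default_factory=_empty_effects)
    param_cv: float = 0.25
    template: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_lesions < 4:
            raise ValueError("need at least 4 lesions")
        n_pos = int(round(self.n_lesions * self.class_balance))
        if min(n_pos, self.n_lesions - n_pos) < 2:
            raise ValueError("every task needs at least 2 lesions per class")
        for task in self.tasks:
            if task not in self.effect_map:
                raise ValueError(f"task {task!r} missing from effect_map")


def generate_cohort(spec: CohortSpec) -> tuple[list[Phantom], pd.DataFrame]:
    """Simulate all lesions and the per-task outcome label table.

    Returns (phantoms, labels) where labels is a tidy DataFrame with columns
    lesion_id, task, label.  Reproducible bit-for-bit under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lesions
    n_pos = int(round(n * spec.class_balance))

    labels = {}
    for task in spec.tasks:
        lab = np.zeros(n, dtype=int)
        lab[rng.choice(n, size=n_pos, replace=False)] = 1
        labels[task] = lab

    # between-lesion biology: lognormal CV on ktrans, a milder CV on ve
    # (kep = ktrans/ve follows), mild CV on R1.  ve is kept in [0.4, 0.95]
    # so every lesion enhances well past the segmentation threshold, as the
    # protocol's segmentable carcinomas do.
    sig_kt = np.sqrt(np.log1p(spec.param_cv ** 2)) if spec.param_cv > 0 else 0.0
    sig_mild = sig_kt / 3.0
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)

    phantoms = []
    for i in range(n):
        mult = {"ktrans": 1.0, "kep": 1.0, "R1": 1.0}
        for task in spec.tasks:
            if labels[task][i] == 1:
                for p, m in spec.effect_map[task].items():
                    if p not in mult:
                        raise ValueError(f"unknown effect parameter {p!r}")
                    mult[p] *= m
        if sig_kt > 0:
            mult["ktrans"] *= float(np.exp(rng.normal(-0.5 * sig_kt ** 2,
                                                      sig_kt)))
            mult["kep"] *= float(np.exp(rng.normal(-0.5 * sig_mild ** 2,
                                                   sig_mild)))
            mult["R1"] *= float(np.exp(rng.normal(-0.5 * sig_mild ** 2,
                                                  sig_mild)))
        t = spec.template
        kt = max(t.true_ktrans * mult["ktrans"], 0.08)
        ve_base = t.true_ktrans / t.true_kep
        ve = float(np.clip(ve_base / mult["kep"], 0.4, 0.95))
        ph_spec = replace(t, true_ktrans=kt, true_kep=kt / ve,
                          true_R1=t.true_R1 * mult["R1"],
                          seed=int(child_seeds[i]))
        phantoms.append(simulate_phantom(ph_spec))

    rows = [(i, task, int(labels[task][i]))
            for task in spec.tasks for i in range(n)]
    table = pd.DataFrame(rows, columns=["lesion_id", "task", "label"])
    return phantoms, table
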