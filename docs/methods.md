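# Methods

## Forward model and simulator

A phantom is a digitized sphere (default radius 9.3 mm, ~1000 voxels at
1.5 mm isotropic spacing on a 24³ grid) on a homogeneous background. Its
signal is produced by the chain the fitting stages invert:

* **Arterial input.** Biexponential population AIF
  Cp(t) = D(a1 e^(−m1 t) + a2 e^(−m2 t)) with a1 = 3.99, a2 = 4.78
  mM·kg/L, m1 = 0.144, m2 = 0.0111 /min, dose D = 0.1 mmol/kg; contrast
  arrives at the end of the first dynamic phase (t = 9 s). Constant and
  custom-sampled AIFs are available for testing.
* **Tissue kinetics.** Standard (one-compartment) Tofts model; the
  convolution is evaluated by exact recursive discretization assuming Cp
  piecewise linear between samples, which is stable and grid-consistent
  (the brute-force fine-grid convolution of the same piecewise-linear
  input agrees to <0.5%).
* **Relaxation and signal.** R1(t) = R1(0) + r1·Ct(t) with contrast
  relaxivity r1 = 4.5 /mM/s (configurable; a representative gadolinium
  value at 3 T), then the SPGR steady-state equation
  S = M0 sin α (1−E1)/(1−E1 cos α), E1 = e^(−TR·R1). Acquisition defaults:
  60 phases at 9 s/phase, dynamic flip angle 20°, VFA set
  {2, 5, 8, 12, 15, 20}°, TR = 5.3 ms.
* **Noise** is additive Gaussian with standard deviation
  noise_sd × per-voxel baseline signal (default cohort setting 0.02).
  Rician noise, motion, B1 inhomogeneity and realistic anatomy are out of
  scope; conclusions from passing tests therefore concern the method's
  numerics and statistics, not robustness to those real-data effects.

Cohorts (default n = 40 lesions, balanced classes) plant multiplicative
effects (default ×1.6 on k^trans for the positive class) on top of
between-lesion biological variability: lognormal with CV 0.25 on k^trans,
CV/3 on ve (k_ep = k^trans/ve derived, ve clipped to [0.4, 0.95]) and CV/3
on R1. The ve floor keeps every lesion's peak relative enhancement above
~0.86 (verified by forward computation), i.e. the cohort emulates lesions
that are segmentable by the 75% enhancement rule, as a contrast-enhanced
carcinoma cohort is by construction. The TIRM-like volume (coarser grid,
4/3 × spacing) scales with ve; the delayed postcontrast volume (finer
grid, 2/3 × spacing) scales with late-time concentration.

All randomness flows from integer seeds through `numpy` SeedSequence
spawning; identical configurations are bit-identical.

## Fitting

* **R1/M0:** linearized DESPOT1 — regress S/sin α on S/tan α; slope = E1.
  Slopes outside (0, 1) flag the voxel invalid (NaN); invalid voxels
  propagate as missing and are excluded from feature statistics.
* **Concentration:** full SPGR inversion for R1(t) using the fitted M0
  (not the small-enhancement linearization), referenced to the first
  (pre-injection) phase so baseline Ct ≡ 0; E1 values pushed outside (0,1)
  by noise are clamped and flagged.
* **Tofts fit:** the model is linear in k^trans, so k^trans is profiled
  out and only k_ep is searched: bounded scalar minimization (three
  restarts across log-spaced subintervals) for single curves; for maps, a
  256-point log-spaced k_ep grid sharing one convolution basis, followed
  by parabolic refinement in log k_ep and re-profiling of k^trans. Bounds:
  k^trans ∈ [0, 5], k_ep ∈ [10⁻³, 10] /min. On noiseless phantoms the
  per-voxel error is ~3×10⁻⁵ relative. ve = k^trans/k_ep, clipped to
  [0, 1] in map output.
* **iAUC:** trapezoidal integral over [onset, onset + 60 s] with linear
  interpolation at the window edges (the 60-s window is a convention, not
  a protocol constant; configurable). Windows past the last phase are
  truncated with a warning.

## Segmentation

Relative enhancement RE = (max over post-baseline phases − baseline) /
baseline, computed per voxel (the maximum-over-phases reading is the
default; "first post-baseline phase" is available). The threshold is
strict (RE > 0.75). Cleanup keeps the largest 26-connected component,
ties broken by the lowest linear voxel index. Resampling to auxiliary
grids is nearest-neighbor in physical coordinates with axis-aligned
geometries only; oblique orientations are rejected outright rather than
silently approximated.

## Features

163 = 9 shape + 7 images × (13 first-order + 9 GLCM).

* Intensities inside the mask are clipped to μ ± 3σ (population σ).
  First-order energy/RMS/moments use the raw clipped values; entropy and
  uniformity use the 256-bin histogram (base-2 logs). Skewness/kurtosis
  at zero variance are defined as 0 (kurtosis is not excess-corrected).
* Quantization: 32 equal-width levels over the post-clip range,
  left-closed bins, constant input → level 1.
* GLCM: a single symmetric matrix merged over all 26 neighbor directions
  at distance 1, normalized to sum 1. Correlation of a degenerate
  (zero-marginal-variance) matrix is defined as 1.
* Shape: surface area by exposed-face counting — deterministic and
  exactly testable, but it overestimates smooth surfaces by ≈3/2, so
  digitized-sphere sphericity plateaus near 0.67 instead of approaching 1
  (a single voxel scores (π/6)^{1/3} ≈ 0.806). Maximum diameter is the
  largest pairwise distance between voxel centers; minimum diameter is
  the smallest principal-axis extent, 2√(3λ_min) of the voxel-center
  covariance (the exact edge length of a uniform distribution along that
  axis). Sphericity and spherical disproportion are exact reciprocals.

## Feature reduction and modeling

* **MIC** is implemented in-package. Fixing one axis's partition makes the
  other axis's optimal partition an additive segmentation problem solved
  exactly by dynamic programming; the exact mode (n ≤ 25) additionally
  enumerates every admissible partition of the fixed axis and is verified
  against independent exhaustive grid enumeration. Above that, the
  standard equipartition heuristic is used on the fixed axis (both
  orientations, best taken). Grid bound nx·ny ≤ n^0.6; deterministic.
* **Reduction:** first feature maximizes |Spearman| with the outcome
  (averaged over 1000 imbalance-adjusted bootstrap resamples by default);
  subsequent features maximize 0.5|ρ| − 0.5·mean MIC against the selected
  set. δ = 0.5 is a design choice (the weighting is not canonical) and is
  exposed. Plain (non-bootstrap) Spearman is available as an option.
* **IABR:** each draw picks a class with probability 1/2, then a member
  uniformly within it — resamples are balanced in expectation (empirical
  positive fraction 0.50 ± 0.03 over 1000 resamples).
* **0.632+ AUC:** per resample, fit in-bag, score out-of-bag; combine the
  apparent AUC with the mean out-of-bag AUC using the no-information value
  γ = 0.5, relative overfitting R = (app − oob)/(app − γ) clamped to
  [0, 1], weight w = 0.632/(1 − 0.368R). Sensitivity/specificity/accuracy
  are taken at the probability-0.5 operating point and combined the same
  way; standard errors are bootstrap-distribution SDs. Resamples with a
  single-class out-of-bag set are redrawn (bounded retries).
* **Logistic fits** are in-package Newton–Raphson maximum likelihood on
  z-standardized features (training-fold statistics, stored in the model
  so external printed-coefficient models can bypass the transform), with
  a 10⁻⁶ ridge fallback under separation, recorded in the model metadata.
* Ties everywhere (gain, AUC, order) break deterministically toward the
  earlier rank / smaller order.

## Known limitation: selection optimism under the null

The 0.632+ estimator itself is calibrated: for a *fixed* feature subset on
null data (n = 40) it averages ≈0.52. The model-building scheme, however,
*maximizes* that estimate — first ranking 163 features by outcome
association, then stepwise-adding the AUC-maximizing feature at each
order — with selection performed outside the bootstrap. Under a null
cohort the maximum over many chance-associated candidates is strongly
optimistic (winner's curse): measured mean final 0.632+ AUC ≈ 0.97 over
10 null seeds at full scale (163 features, 25 reduced, orders 1–10,
n = 40). Out-of-bag evaluation cannot remove this because the selected
features' chance associations live in the same subjects that form the
out-of-bag sets. Null-cohort results from this scheme must therefore be
interpreted against a selection-aware permutation baseline, not against
0.5. The acceptance suite reports this quantity honestly rather than
adjusting it.

## Problem sizes used in the tests

The full-pipeline checks run the default study conditions (40 lesions of
~1000 voxels, n_boot = 100); property tests use smaller phantoms (16³
grids, ~123-voxel lesions) and feature-table-level cohorts where the
property under test concerns the statistics rather than the imaging
chain. Simulation-study tests (planted-feature recovery) use 20 seeds at
n_boot = 25; all sizes are stated in the tests themselves.
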