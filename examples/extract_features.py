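"""Extract the full 163-feature radiomic vector for one lesion.

Runs the whole per-lesion chain: segmentation, pharmacokinetic mapping,
mask resampling to the TIRM-like and postcontrast grids, then 9 shape +
7 x 22 intensity/texture features.
"""

from pkradiomics import PhantomSpec, simulate_phantom
from pkradiomics.pipeline import phantom_features

phantom = simulate_phantom(PhantomSpec(noise_sd=0.02, seed=4))
feats = phantom_features(phantom)

print(f"total features: {len(feats)}")
shape = {k: v for k, v in feats.items() if k.startswith("shape__")}
print(f"shape features ({len(shape)}):")
for k in ("shape__volume", "shape__surface_area", "shape__sphericity"):
    print(f"  {k:<28} {feats[k]:10.3f}")
print("selected intensity/texture features:")
for k in ("ktrans__mean", "ktrans__median", "kep__mean",
          "ktrans__glcm_entropy", "iauc__glcm_variance", "r1__uniformity"):
    print(f"  {k:<28} {feats[k]:10.4f}")
# Names follow <image>__<feature>; ktrans__mean is the mean transfer
# constant (1/min) inside the tumor mask after mu +/- 3 sigma clipping,
# glcm_* features come from the 32-level 3D cooccurrence matrix.
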