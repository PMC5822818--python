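"""Simulate one contrast-enhancing lesion and segment it by the 75% rule.

Builds a spherical-lesion phantom with the forward Tofts + SPGR physics,
computes the relative-enhancement map and recovers the lesion with the
enhancement-threshold segmentation.
"""

import numpy as np

from pkradiomics import PhantomSpec, relative_enhancement, segment_lesion, simulate_phantom
from pkradiomics.pipeline import lesion_bbox_from_truth

phantom = simulate_phantom(PhantomSpec(noise_sd=0.02, seed=11))
lesion = phantom.mask.data.astype(bool)

re = relative_enhancement(phantom.series).data
print(f"lesion voxels (truth):        {int(lesion.sum())}")
print(f"peak enhancement in lesion:   {np.nanmax(re[lesion]):.2f} "
      "(fraction of baseline signal)")
print(f"peak enhancement outside:     {np.nanmax(re[~lesion]):.2f}")

mask = segment_lesion(phantom.series, lesion_bbox_from_truth(phantom),
                      threshold=0.75)
inter = np.logical_and(mask.data, lesion).sum()
dice = 2 * inter / (mask.n_voxels + lesion.sum())
print(f"segmented voxels:             {mask.n_voxels}")
print(f"Dice overlap with truth:      {dice:.3f}")
# A Dice of 1.0 means the enhancement rule recovered the planted sphere
# exactly; with 2% signal noise a stray boundary voxel may differ.
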