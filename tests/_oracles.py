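"""Shared independent oracles and fixture builders for the test suite."""

import numpy as np

from pkradiomics import ImageVolume, TumorMask


def brute_force_glcm(levels, mask, n_levels):
    """Triple-loop cooccurrence pair counter over all 26 neighbor offsets."""
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
               for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in offsets:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < shape[0] and 0 <= v < shape[1] \
                            and 0 <= w < shape[2] and mask[u, v, w]:
                        counts[levels[x, y, z] - 1, levels[u, v, w] - 1] += 1
    return counts / counts.sum()


def lesion_images(rng, n=6):
    """A digitized-sphere mask plus seven random intensity volumes."""
    arr = np.zeros((n, n, n))
    c = n // 2
    x, y, z = np.ogrid[:n, :n, :n]
    lesion = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= (c - 0.5) ** 2
    mask = TumorMask.from_array(lesion.astype(float))
    images = {name: ImageVolume(rng.normal(10, 2, (n, n, n)))
              for name in ("r1", "ktrans", "kep", "ve", "iauc", "tirm",
                           "postc")}
    return images, mask
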