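"""Radiomic features: normalization, quantization, shape, first-order,
GLCM — each checked against independent definitional oracles."""

import numpy as np
import pytest

from pkradiomics import (ImageVolume, TumorMask, extract_all,
                         first_order_features, glcm_features, glcm_matrix,
                         normalize_intensities, quantize, shape_features)
from pkradiomics.features import (FIRST_ORDER_NAMES, GLCM_NAMES, SHAPE_NAMES,
                                  DegenerateMatrixError, _DIRECTIONS)


def _vol_mask(data, mask=None, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(data, dtype=float)
    img = ImageVolume(data, spacing)
    m = np.ones_like(data) if mask is None else np.asarray(mask, dtype=float)
    return img, TumorMask.from_array(m, spacing)


class TestNormalize:
    def test_constant_image_is_noop(self):
        img, m = _vol_mask(np.full((3, 3, 3), 5.0))
        np.testing.assert_array_equal(normalize_intensities(img, m), 5.0)

    def test_outlier_clipped_to_three_sigma(self):
        vals = np.zeros(100)
        vals[-1] = 1000.0
        img, m = _vol_mask(vals.reshape(4, 5, 5))
        mu, sd = vals.mean(), vals.std()
        out = normalize_intensities(img, m)
        assert out.max() == pytest.approx(mu + 3 * sd)
        assert (out <= mu + 3 * sd).all()

    def test_in_range_values_unchanged(self, rng):
        data = rng.normal(0, 1, (4, 4, 4))
        img, m = _vol_mask(data)
        vals = data.ravel()
        inside = np.abs(vals - vals.mean()) <= 3 * vals.std()
        out = normalize_intensities(img, m)
        np.testing.assert_array_equal(np.sort(out)[inside.sum() and None:],
                                      np.sort(out)[inside.sum() and None:])
        assert np.isin(vals[inside], out).all()


class TestQuantize:
    def test_endpoints(self):
        np.testing.assert_array_equal(quantize([0.0, 1.0], 2), [1, 2])

    def test_constant_maps_to_level_one(self):
        np.testing.assert_array_equal(quantize([3.0, 3.0, 3.0], 8), 1)

    def test_hand_computed_bins(self):
        # bins over [0,1] width .25: 0 -> 1, 0.5 -> 3 (left-closed), 1 -> 4
        np.testing.assert_array_equal(quantize([0.0, 0.5, 1.0], 4), [1, 3, 4])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantize([], 4)


class TestShapeFeatures:
    def test_single_voxel(self):
        m = TumorMask.from_array(np.pad(np.ones((1, 1, 1)), 1))
        f = shape_features(m)
        assert f["n_voxels"] == 1 and f["volume"] == 1.0
        assert f["surface_area"] == 6.0
        assert f["max_diameter"] == 0.0
        assert f["sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3))

    def test_two_adjacent_voxels(self):
        arr = np.zeros((4, 3, 3))
        arr[1, 1, 1] = arr[2, 1, 1] = 1
        f = shape_features(TumorMask.from_array(arr))
        assert f["n_voxels"] == 2 and f["volume"] == 2.0
        assert f["surface_area"] == 10.0
        assert f["max_diameter"] == 1.0

    def test_sphericity_reciprocal_of_disproportion(self, rng):
        arr = (rng.random((6, 6, 6)) > 0.5).astype(float)
        arr[3, 3, 3] = 1
        from pkradiomics import keep_largest_component
        m = keep_largest_component(TumorMask.from_array(arr))
        f = shape_features(m)
        assert f["sphericity"] == pytest.approx(
            1.0 / f["spherical_disproportion"], rel=1e-12)

    def test_anisotropic_spacing_in_physical_units(self):
        arr = np.zeros((3, 3, 3))
        arr[1, 1, 1] = 1
        f = shape_features(TumorMask.from_array(arr, spacing=(1.0, 1.0, 3.6)))
        assert f["volume"] == pytest.approx(3.6)
        assert f["surface_area"] == pytest.approx(2 * 3.6 + 2 * 3.6 + 2 * 1.0)

    def test_digitized_sphere_sphericity_bounded_and_stable(self):
        # exposed-face surface area overestimates a smooth sphere, so
        # sphericity plateaus near 0.67 rather than approaching 1
        vals = []
        for r in (3.0, 5.0, 7.0, 9.0):
            n = int(2 * r + 5)
            c = n // 2
            x, y, z = np.ogrid[:n, :n, :n]
            arr = (((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
                   <= r ** 2).astype(float)
            vals.append(shape_features(TumorMask.from_array(arr))["sphericity"])
        assert all(0.6 < v < 1.05 for v in vals)
        assert abs(vals[-1] - vals[-2]) < 0.05    # converged plateau

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(TumorMask.from_array(np.zeros((2, 2, 2))))


class TestFirstOrder:
    def test_constant_conventions(self):
        f = first_order_features(np.full(10, 3.0))
        assert f["entropy"] == 0.0 and f["uniformity"] == 1.0
        assert f["variance"] == 0.0 and f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0

    def test_hand_arithmetic(self):
        f = first_order_features(np.array([1.0, 2.0, 2.0]))
        assert f["energy"] == 9.0
        assert f["mean"] == pytest.approx(5 / 3)
        assert f["median"] == 2.0

    def test_uniform_eight_levels(self):
        f = first_order_features(np.arange(1.0, 9.0))
        assert f["entropy"] == pytest.approx(3.0)
        assert f["uniformity"] == pytest.approx(1 / 8)

    def test_matches_definitional_oracle(self, rng):
        """50 random vectors against direct formulas, tolerance 1e-12."""
        for _ in range(50):
            x = rng.normal(0, rng.uniform(0.5, 3), rng.integers(5, 60))
            f = first_order_features(x)
            n = x.size
            mean = sum(x) / n
            var = sum((v - mean) ** 2 for v in x) / n
            assert f["energy"] == pytest.approx(sum(v * v for v in x),
                                                rel=1e-12)
            assert f["rms"] == pytest.approx((sum(v * v for v in x) / n) ** 0.5,
                                             rel=1e-12)
            assert f["mean"] == pytest.approx(mean, rel=1e-12, abs=1e-12)
            assert f["variance"] == pytest.approx(var, rel=1e-12, abs=1e-12)
            assert f["mad"] == pytest.approx(
                sum(abs(v - mean) for v in x) / n, rel=1e-12)
            if var > 0:
                assert f["skewness"] == pytest.approx(
                    sum((v - mean) ** 3 for v in x) / n / var ** 1.5, rel=1e-9)
                assert f["kurtosis"] == pytest.approx(
                    sum((v - mean) ** 4 for v in x) / n / var ** 2, rel=1e-9)
            # histogram-based: direct recount
            hist, _ = np.histogram(x, bins=256, range=(x.min(), x.max()))
            p = hist[hist > 0] / n
            assert f["entropy"] == pytest.approx(-(p * np.log2(p)).sum(),
                                                 rel=1e-12)
            assert f["uniformity"] == pytest.approx((p ** 2).sum(), rel=1e-12)


from _oracles import brute_force_glcm  # noqa: E402


class TestGLCM:
    def test_constant_region_is_diagonal_point_mass(self):
        lev = np.ones((3, 3, 3), dtype=int)
        _, m = _vol_mask(np.ones((3, 3, 3)))
        P = glcm_matrix(lev, m, n_levels=2)
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_two_voxel_symmetric_pair(self):
        lev = np.zeros((2, 1, 1), dtype=int)
        lev[0, 0, 0], lev[1, 0, 0] = 1, 2
        _, m = _vol_mask(np.ones((2, 1, 1)))
        P = glcm_matrix(lev, m, n_levels=2)
        assert P[0, 1] == 0.5 and P[1, 0] == 0.5

    def test_single_voxel_degenerate(self):
        lev = np.ones((1, 1, 1), dtype=int)
        _, m = _vol_mask(np.ones((1, 1, 1)))
        with pytest.raises(DegenerateMatrixError):
            glcm_matrix(lev, m, n_levels=2)

    def test_matches_brute_force_oracle(self, rng):
        """50 random <= 6^3 level volumes, exact pair counts."""
        for _ in range(50):
            shape = tuple(rng.integers(2, 7, 3))
            lev = rng.integers(1, 5, shape)
            mask = rng.random(shape) > 0.3
            if mask.sum() < 2:
                mask[0, 0, 0] = mask[0, 0, 1 if shape[2] > 1 else 0] = True
            m = TumorMask.from_array(mask.astype(float))
            try:
                P = glcm_matrix(lev, m, n_levels=4)
            except DegenerateMatrixError:
                continue
            expected = brute_force_glcm(lev, mask, 4)
            np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_thirteen_unique_directions(self):
        assert len(_DIRECTIONS) == 13


class TestGLCMFeatures:
    def test_point_mass_matrix(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0                       # level k = 3
        f = glcm_features(P)
        assert f["glcm_energy"] == 1.0 and f["glcm_contrast"] == 0.0
        assert f["glcm_entropy"] == 0.0 and f["glcm_homogeneity"] == 1.0
        assert f["glcm_dissimilarity"] == 0.0
        assert f["glcm_autocorrelation"] == 9.0
        assert f["glcm_sum_average"] == 6.0
        assert f["glcm_correlation"] == 1.0   # degenerate-by-convention

    def test_uniform_two_by_two(self):
        P = np.full((2, 2), 0.25)
        f = glcm_features(P)
        assert f["glcm_energy"] == 0.25
        assert f["glcm_entropy"] == pytest.approx(2.0)
        assert f["glcm_contrast"] == pytest.approx(0.5)
        assert f["glcm_correlation"] == pytest.approx(0.0)

    def test_matches_summation_oracle(self, rng):
        """Random matrices against direct definitional sums, 1e-12."""
        for _ in range(50):
            n = int(rng.integers(2, 8))
            P = rng.random((n, n))
            P = (P + P.T)
            P /= P.sum()
            f = glcm_features(P)
            e = c = h = d = ac = ent = 0.0
            for i in range(1, n + 1):
                for j in range(1, n + 1):
                    p = P[i - 1, j - 1]
                    e += p * p
                    c += (i - j) ** 2 * p
                    h += p / (1 + abs(i - j))
                    d += abs(i - j) * p
                    ac += i * j * p
                    if p > 0:
                        ent -= p * np.log2(p)
            assert f["glcm_energy"] == pytest.approx(e, rel=1e-12)
            assert f["glcm_contrast"] == pytest.approx(c, rel=1e-12)
            assert f["glcm_homogeneity"] == pytest.approx(h, rel=1e-12)
            assert f["glcm_dissimilarity"] == pytest.approx(d, rel=1e-12)
            assert f["glcm_autocorrelation"] == pytest.approx(ac, rel=1e-12)
            assert f["glcm_entropy"] == pytest.approx(ent, rel=1e-12)
            mu_i = sum(i * P[i - 1, :].sum() for i in range(1, n + 1))
            sa = sum((i + j) * P[i - 1, j - 1] for i in range(1, n + 1)
                     for j in range(1, n + 1))
            assert f["glcm_sum_average"] == pytest.approx(sa, rel=1e-12)
            var = sum((i - mu_i) ** 2 * P[i - 1, j - 1]
                      for i in range(1, n + 1) for j in range(1, n + 1))
            assert f["glcm_variance"] == pytest.approx(var, rel=1e-12)


from _oracles import lesion_images as _lesion_images  # noqa: E402


class TestExtractAll:
    def test_full_set_has_163_features(self, rng):
        images, mask = _lesion_images(rng)
        feats = extract_all(images, mask)
        assert len(feats) == 163
        assert sum(1 for k in feats if k.startswith("shape__")) == 9
        assert len(set(feats)) == 163

    def test_six_images_gives_141(self, rng):
        images, mask = _lesion_images(rng)
        images.pop("tirm")
        feats = extract_all(images, mask)
        assert len(feats) == 9 + 6 * 22
        assert not any(k.startswith("tirm__") for k in feats)

    def test_intensity_shift_invariance(self, rng):
        images, mask = _lesion_images(rng)
        shifted = {k: ImageVolume(v.data + 100.0, v.spacing, v.origin)
                   for k, v in images.items()}
        a = extract_all(images, mask)
        b = extract_all(shifted, mask)
        for name in a:
            base = name.split("__")[1]
            if base.startswith("glcm_") or base in ("entropy", "uniformity",
                                                    "std", "variance", "mad",
                                                    "skewness", "kurtosis") \
                    or name.startswith("shape__"):
                assert b[name] == pytest.approx(a[name], rel=1e-9), name
            elif base in ("mean", "median", "min", "max"):
                assert b[name] == pytest.approx(a[name] + 100.0, rel=1e-9)

    def test_rotation_invariance_of_all_features(self, rng):
        """90-degree axis rotations leave all 163 features unchanged
        (isotropic spacing)."""
        images, mask = _lesion_images(rng)
        a = extract_all(images, mask)
        rot_imgs = {k: ImageVolume(np.rot90(v.data, k=1, axes=(0, 1)))
                    for k, v in images.items()}
        rot_mask = TumorMask.from_array(
            np.rot90(mask.volume.data, k=1, axes=(0, 1)))
        b = extract_all(rot_imgs, rot_mask)
        for name in a:
            assert b[name] == pytest.approx(a[name], rel=1e-9), name

    def test_geometry_mismatch_names_offending_image(self, rng):
        images, mask = _lesion_images(rng)
        images["kep"] = ImageVolume(images["kep"].data,
                                    spacing=(2.0, 2.0, 2.0))
        with pytest.raises(Exception, match="kep"):
            extract_all(images, mask)

    def test_name_scheme(self, rng):
        images, mask = _lesion_images(rng)
        feats = extract_all(images, mask)
        for fo in FIRST_ORDER_NAMES:
            assert f"ktrans__{fo}" in feats
        for g in GLCM_NAMES:
            assert f"iauc__{g}" in feats
        for s in SHAPE_NAMES:
            assert f"shape__{s}" in feats
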