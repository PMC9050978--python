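"""Radiomic feature extraction: hand-worked fixtures, brute-force oracle
equivalence, shape limits, and the invariances the features must satisfy."""

import math

import numpy as np
import pytest
from skimage import morphology

import lungrad as lr
from lungrad.features import DiscretizedROI, _DIRECTIONS

from _oracles import (
    first_order_bruteforce,
    glcm_bruteforce,
    glcm_stats_bruteforce,
    glrlm_bruteforce,
    run_length_stats_bruteforce,
)


def droi_from_array(levels, mask=None, n_bins=None):
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    n_bins = n_bins or int(levels.max())
    return DiscretizedROI(np.where(mask, levels, 0), np.asarray(mask, bool), n_bins)


class TestDiscretize:
    def test_constant_roi_maps_to_level_one(self):
        img = lr.GrayImage(np.full((5, 5), 42.0))
        mask = lr.LesionMask(np.ones((5, 5), bool))
        droi = lr.discretize(img, mask, 8)
        assert (droi.in_mask == 1).all()

    def test_full_range_is_bijective(self):
        img = lr.GrayImage(np.arange(32, dtype=float).reshape(4, 8))
        mask = lr.LesionMask(np.ones((4, 8), bool))
        droi = lr.discretize(img, mask, 32)
        assert sorted(droi.in_mask) == list(range(1, 33))

    def test_endpoints_map_to_extreme_bins(self):
        img = lr.GrayImage(np.array([[0.0, 10.0]]))
        mask = lr.LesionMask(np.ones((1, 2), bool))
        droi = lr.discretize(img, mask, 4)
        assert set(droi.in_mask) == {1, 4}

    def test_empty_mask_raises(self):
        img = lr.GrayImage(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            lr.discretize(img, lr.LesionMask(np.zeros((3, 3), bool)), 8)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        px = rng.normal(100, 20, (16, 16))
        mask = lr.LesionMask(rng.random((16, 16)) < 0.7)
        a = lr.discretize(lr.GrayImage(px), mask, 32)
        b = lr.discretize(lr.GrayImage(px + 137.5), mask, 32)
        np.testing.assert_array_equal(a.levels, b.levels)


class TestFirstOrder:
    def test_hand_worked_histogram(self):
        # levels [1,1,2,4]: mu=2, m2=1.5, m4=4.5 -> kurtosis 2.0; energy 0.375
        droi = droi_from_array([[1, 1], [2, 4]], n_bins=4)
        var, kurt, energy = lr.first_order(droi)
        assert var == pytest.approx(1.5, abs=1e-12)
        assert kurt == pytest.approx(2.0, abs=1e-12)
        assert energy == pytest.approx(0.375, abs=1e-12)

    def test_matches_direct_moment_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            levels = rng.integers(1, 9, size=rng.integers(4, 40))
            droi = droi_from_array(levels.reshape(1, -1), n_bins=8)
            got = lr.first_order(droi)
            expected = first_order_bruteforce(levels)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_uniform_histogram_energy(self):
        droi = droi_from_array(np.arange(1, 9).reshape(2, 4), n_bins=8)
        assert lr.first_order(droi)[2] == pytest.approx(1 / 8)

    def test_gaussian_levels_pearson_kurtosis_near_3(self):
        rng = np.random.default_rng(2)
        x = np.clip(np.round(rng.normal(100, 12, 100_000)), 40, 160)
        img = lr.GrayImage(x.reshape(250, 400))
        droi = lr.discretize(img, lr.LesionMask(np.ones((250, 400), bool)), 64)
        _, kurt, _ = lr.first_order(droi)
        assert kurt == pytest.approx(3.0, abs=0.2)

    def test_zero_variance_raises(self):
        droi = droi_from_array([[1, 1], [1, 1]], n_bins=4)
        with pytest.raises(ValueError, match="degenerate"):
            lr.first_order(droi)


class TestShape:
    def test_disk_circularity_near_one(self):
        mask = lr.LesionMask(np.pad(morphology.disk(50), 3))
        assert 0.95 <= lr.shape_circularity(mask) <= 1.05

    def test_square_circularity_near_pi_over_4(self):
        px = np.zeros((60, 60), bool)
        px[10:50, 10:50] = True
        assert lr.shape_circularity(lr.LesionMask(px)) == pytest.approx(math.pi / 4, abs=0.05)

    def test_spiculation_lowers_circularity(self, disk_phantom, spiculated_phantom):
        assert (lr.shape_circularity(spiculated_phantom[1])
                < lr.shape_circularity(disk_phantom[1]))

    def test_multi_component_mask_rejected(self):
        px = np.zeros((10, 10), bool)
        px[1:3, 1:3] = True
        px[7:9, 7:9] = True
        with pytest.raises(ValueError, match="components"):
            lr.shape_circularity(lr.LesionMask(px))

    @pytest.mark.parametrize("axes_mm, expected", [
        ((10, 6), 8),       # mean 8
        ((21, 21), 21),     # circle
        ((9, 6), 8),        # 7.5 rounds half-up
    ])
    def test_diameter_of_analytic_ellipse(self, axes_mm, expected):
        # rasterize finely (0.1 mm pixels) so the moment axes are accurate
        sp = 0.1
        a, b = axes_mm[0] / 2 / sp, axes_mm[1] / 2 / sp
        n = int(2 * max(a, b)) + 20
        yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2
        px = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
        assert lr.lesion_diameter(lr.LesionMask(px, (sp, sp))) == expected

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            lr.lesion_diameter(lr.LesionMask(np.zeros((5, 5), bool)))


class TestGLCM:
    def test_hand_enumerated_two_by_two(self):
        droi = droi_from_array([[1, 1], [1, 2]], n_bins=2)
        m = lr.glcm(droi, distance=1, directions=(0,))
        np.testing.assert_allclose(m.P, [[0.5, 0.25], [0.25, 0.0]])
        shade, max_prob = lr.glcm_features(m)
        assert max_prob == pytest.approx(0.5)
        assert shade == pytest.approx(0.0, abs=1e-12)

    def test_constant_roi(self):
        droi = droi_from_array(np.ones((3, 3), int), n_bins=2)
        m = lr.glcm(droi)
        assert m.P[0, 0] == pytest.approx(1.0)
        shade, max_prob = lr.glcm_features(m)
        assert (shade, max_prob) == (pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))

    def test_single_pixel_has_no_pair(self):
        droi = droi_from_array([[1]], n_bins=2)
        with pytest.raises(ValueError, match="pair"):
            lr.glcm(droi)

    def test_matches_bruteforce_enumeration(self):
        from conftest import random_roi
        rng = np.random.default_rng(3)
        for _ in range(30):
            levels, mask = random_roi(rng, max_side=8)
            droi = droi_from_array(levels, mask, n_bins=int(levels.max()) or 1)
            if np.count_nonzero(mask) < 2:
                continue
            try:
                m = lr.glcm(droi)
            except ValueError:
                continue
            expected = glcm_bruteforce(levels, mask)
            np.testing.assert_allclose(m.P, expected, atol=1e-14)
            got = lr.glcm_features(m)
            want = glcm_stats_bruteforce(expected)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_symmetry_and_normalization(self):
        from conftest import random_roi
        rng = np.random.default_rng(4)
        levels, mask = random_roi(rng, max_side=10)
        droi = droi_from_array(levels, mask, n_bins=int(levels.max()))
        m = lr.glcm(droi)
        assert m.P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(m.P, m.P.T)


class TestGLRLM:
    def test_hand_enumerated_runs(self):
        levels = np.array([[1, 1, 2], [2, 2, 2], [3, 3, 3]])
        droi = droi_from_array(levels, np.ones((3, 3), bool), n_bins=3)
        mats = lr.glrlm(droi, directions=(0,))
        R = mats[0].R
        assert mats[0].n_runs == 4
        assert R[0, 1] == 1        # level 1, length 2
        assert R[1, 0] == 1        # level 2, length 1
        assert R[1, 2] == 1        # level 2, length 3
        assert R[2, 2] == 1        # level 3, length 3
        lre, longhem = lr.glrlm_features(mats)
        assert lre == pytest.approx(5.75)
        assert longhem == pytest.approx(31.25)

    def test_single_pixel_single_run(self):
        droi = droi_from_array([[2]], np.ones((1, 1), bool), n_bins=2)
        mats = lr.glrlm(droi, directions=(0,))
        assert mats[0].n_runs == 1
        assert mats[0].R[1, 0] == 1

    def test_all_runs_length_one_gives_lre_one(self):
        levels = np.array([[1, 2, 1, 2]])
        droi = droi_from_array(levels, np.ones((1, 4), bool), n_bins=2)
        lre, _ = lr.glrlm_features(lr.glrlm(droi, directions=(0,)))
        assert lre == pytest.approx(1.0)

    def test_matches_bruteforce_all_directions(self):
        from conftest import random_roi
        rng = np.random.default_rng(5)
        for _ in range(30):
            levels, mask = random_roi(rng, max_side=8)
            droi = droi_from_array(levels, mask, n_bins=int(levels.max()))
            mats = lr.glrlm(droi)
            for m in mats:
                expected = glrlm_bruteforce(levels, mask, m.direction)
                got = m.R[: expected.shape[0], : expected.shape[1]]
                np.testing.assert_array_equal(got, expected)
                assert m.R[expected.shape[0]:, :].sum() == 0
                assert m.R[:, expected.shape[1]:].sum() == 0


class TestWavelet:
    def test_constant_roi_matches_subband_pipeline_oracle(self):
        img = lr.GrayImage(np.full((8, 8), 10.0))
        mask = lr.LesionMask(np.ones((8, 8), bool))
        got = lr.wavelet_approx_lre(img, mask, n_bins=4)
        # constant image -> constant LL subband -> every line one full-length run
        import pywt
        ll, _ = pywt.dwt2(np.full((8, 8), 10.0), "haar")
        side = ll.shape[0]
        # 0/90: `side` runs of length `side`; diagonals: 2*side-1 runs, lengths 1..side..1
        lre_axis = side**2
        diag_lengths = np.concatenate([np.arange(1, side + 1), np.arange(side - 1, 0, -1)])
        lre_diag = float(np.mean([(diag_lengths**2 * 1).sum() / len(diag_lengths)]))
        expected = np.mean([lre_axis, lre_axis, lre_diag, lre_diag])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_coarse_texture_raises_a_lre(self):
        fine_img, fine_mask = lr.make_lesion_phantom(
            lr.PhantomConfig(seed=11, texture_corr_len=1.0))
        coarse_img, coarse_mask = lr.make_lesion_phantom(
            lr.PhantomConfig(seed=11, texture_corr_len=8.0))
        assert (lr.wavelet_approx_lre(coarse_img, coarse_mask)
                > lr.wavelet_approx_lre(fine_img, fine_mask))

    def test_one_pixel_wide_roi_rejected(self):
        img = lr.GrayImage(np.random.default_rng(0).random((1, 10)))
        mask = lr.LesionMask(np.ones((1, 10), bool))
        with pytest.raises(ValueError, match="2x2"):
            lr.wavelet_approx_lre(img, mask)


class TestExtractAll:
    def test_disk_phantom_fields_finite(self, disk_phantom):
        fv = lr.extract_all(*disk_phantom)
        assert fv.circularity >= 0.95
        vals = list(fv.as_dict().values())
        assert np.isfinite(vals).all()
        assert 0 < fv.energy <= 1
        assert 0 < fv.maximum_probability <= 1

    def test_deterministic(self, disk_phantom):
        assert lr.extract_all(*disk_phantom) == lr.extract_all(*disk_phantom)

    def test_single_pixel_mask_names_failing_feature(self, disk_phantom):
        img = disk_phantom[0]
        px = np.zeros(img.shape, bool)
        px[10, 10] = True
        with pytest.raises(RuntimeError, match="feature '"):
            lr.extract_all(img, lr.LesionMask(px))


class TestInvariances:
    def test_rotation_by_90_preserves_direction_averaged_features(self):
        from conftest import random_roi
        rng = np.random.default_rng(6)
        for _ in range(5):
            levels, mask = random_roi(rng, max_side=10)
            droi = droi_from_array(levels, mask, n_bins=int(levels.max()))
            rot = droi_from_array(np.rot90(levels), np.rot90(mask),
                                  n_bins=int(levels.max()))
            try:
                a = lr.glcm_features(lr.glcm(droi))
                b = lr.glcm_features(lr.glcm(rot))
            except ValueError:
                continue
            assert a == pytest.approx(b, rel=1e-12, abs=1e-12)
            ra = lr.glrlm_features(lr.glrlm(droi))
            rb = lr.glrlm_features(lr.glrlm(rot))
            assert ra == pytest.approx(rb, rel=1e-12)

    def test_intensity_shift_leaves_features_unchanged(self, disk_phantom):
        img, mask = disk_phantom
        shifted = lr.GrayImage(img.pixels + 500.0, img.spacing)
        a = lr.extract_all(img, mask)
        b = lr.extract_all(shifted, mask)
        for name, val in a.as_dict().items():
            assert val == pytest.approx(b.as_dict()[name], rel=1e-9), name

    def test_longhem_tracks_texture_correlation_length(self):
        from scipy import stats
        corr_lens = np.linspace(0.5, 8.0, 20)
        vals = []
        for cl in corr_lens:
            # fixed seed and noise-free background: the sweep isolates the
            # correlation-length effect on the lesion texture itself
            img, mask = lr.make_lesion_phantom(
                lr.PhantomConfig(seed=100, texture_corr_len=float(cl),
                                 background_sd=0.0))
            droi = lr.discretize(img, mask, 32)
            _, longhem = lr.glrlm_features(lr.glrlm(droi))
            vals.append(longhem)
        rho = stats.spearmanr(corr_lens, vals).statistic
        assert rho > 0.8

    def test_circularity_tracks_spiculation(self):
        from scipy import stats
        amps = np.linspace(0, 0.3, 20)
        vals = []
        for k, a in enumerate(amps):
            _, mask = lr.make_lesion_phantom(
                lr.PhantomConfig(seed=200 + k, spiculation_amp=float(a)))
            vals.append(lr.shape_circularity(mask))
        rho = stats.spearmanr(amps, vals).statistic
        assert rho < -0.8
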