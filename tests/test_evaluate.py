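import math
import warnings

import numpy as np
import pytest

from fastpet.evaluate import (
    compare_features,
    cov,
    fd_histogram,
    glcm_features,
    intensity_features,
    nema_rois,
    recovery_coefficient,
    voxelwise_mean_std,
)
from fastpet.geometry import VoxelGrid
from fastpet.phantom import VolumeImage


@pytest.fixture
def grid8():
    return VoxelGrid(8, 8, 8, 2.0, 2.0, 2.0)


def _img(grid, values):
    return VolumeImage(np.asarray(values, float), grid, "reconstructed")


class TestRecoveryCoefficient:
    def test_perfect_recovery_is_one(self, grid8):
        roi = np.zeros(grid8.shape, bool)
        roi[2:5, 2:5, 2:5] = True
        img = _img(grid8, np.full(grid8.shape, 42.0))
        assert recovery_coefficient(img, roi, 42.0) == pytest.approx(1.0)

    def test_zero_image_gives_zero(self, grid8):
        roi = np.ones(grid8.shape, bool)
        assert recovery_coefficient(_img(grid8, np.zeros(grid8.shape)), roi, 5.0) == 0.0

    def test_empty_roi_rejected(self, grid8):
        with pytest.raises(ValueError):
            recovery_coefficient(_img(grid8, np.ones(grid8.shape)), np.zeros(grid8.shape, bool), 1.0)

    def test_ground_truth_nema_large_sphere_rc_near_one(self):
        """Exact ROI on the ground-truth map at 1.65 mm voxels: only
        rasterization edge mixing lowers the 37 mm sphere RC."""
        from fastpet.phantom import make_nema_iq

        grid = VoxelGrid(200, 200, 40, 1.65, 1.65, 1.646)
        act, _, spec = make_nema_iq(grid)
        rois = nema_rois(grid, spec)
        rc = recovery_coefficient(act, rois.spheres[37.0], 27369.0)
        assert 0.97 <= rc <= 1.0


class TestCov:
    def test_constant_image_zero(self, grid8):
        roi = np.ones(grid8.shape, bool)
        assert cov(_img(grid8, np.full(grid8.shape, 3.0)), roi) == 0.0

    def test_two_voxel_hand_value(self, grid8):
        v = np.zeros(grid8.shape)
        roi = np.zeros(grid8.shape, bool)
        v[0, 0, 0], v[0, 0, 1] = 1.0, 3.0
        roi[0, 0, 0] = roi[0, 0, 1] = True
        assert cov(_img(grid8, v), roi) == pytest.approx(0.5)

    def test_scale_invariance(self, grid8, rng):
        v = rng.random(grid8.shape) + 0.5
        roi = np.ones(grid8.shape, bool)
        assert cov(_img(grid8, v), roi) == pytest.approx(cov(_img(grid8, 7.3 * v), roi))

    def test_zero_mean_rejected(self, grid8):
        roi = np.ones(grid8.shape, bool)
        with pytest.raises(ValueError):
            cov(_img(grid8, np.zeros(grid8.shape)), roi)


class TestVoxelwiseMeanStd:
    def test_identical_realizations_zero_std(self, grid8, rng):
        img = _img(grid8, rng.random(grid8.shape))
        mean, std = voxelwise_mean_std([img, img, img])
        assert np.allclose(mean.values, img.values, rtol=1e-14)
        assert std.values.max() < 1e-12

    def test_hand_values_and_order_invariance(self, grid8):
        a = _img(grid8, np.zeros(grid8.shape))
        b = _img(grid8, np.full(grid8.shape, 2.0))
        m1, s1 = voxelwise_mean_std([a, b])
        m2, s2 = voxelwise_mean_std([b, a])
        assert np.all(m1.values == 1.0) and np.all(s1.values == 1.0)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(s1.values, s2.values)

    def test_single_realization_rejected(self, grid8):
        with pytest.raises(ValueError):
            voxelwise_mean_std([_img(grid8, np.zeros(grid8.shape))])


class TestFdHistogram:
    def test_hand_computed_bin_width(self):
        # n = 8, IQR = 4 -> width 2*4*8^(-1/3) = 4.0
        v = np.array([0.0, 1, 2, 3, 4, 5, 6, 7])
        edges, counts = fd_histogram(v)
        width = 2 * (np.percentile(v, 75) - np.percentile(v, 25)) * 8 ** (-1 / 3)
        assert np.diff(edges)[0] == pytest.approx(width)
        assert counts.sum() == 8

    def test_constant_data_single_bin(self):
        edges, counts = fd_histogram(np.full(10, 3.3))
        assert len(counts) == 1 and counts[0] == 10

    def test_counts_sum_to_n(self, rng):
        v = rng.normal(size=500)
        _, counts = fd_histogram(v)
        assert counts.sum() == 500

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fd_histogram(np.array([1.0]))


class TestIntensityFeatures:
    def test_constant_roi(self, grid8):
        roi = np.zeros(grid8.shape, bool)
        roi[2:6, 2:6, 2:6] = True
        fv = intensity_features(_img(grid8, np.full(grid8.shape, 5.0)), roi)
        assert fv.skewness == 0.0
        assert fv.peak == pytest.approx(fv.mean) == pytest.approx(5.0)
        assert fv.cov == 0.0

    def test_skewness_brute_force_value(self, grid8):
        """{1,1,1,10}: m3/m2^1.5 = 1.1547 (biased moment form)."""
        v = np.zeros(grid8.shape)
        roi = np.zeros(grid8.shape, bool)
        for i, val in enumerate([1.0, 1.0, 1.0, 10.0]):
            v[0, 0, i] = val
            roi[0, 0, i] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny ROI clips the peak sphere
            fv = intensity_features(_img(grid8, v), roi)
        x = np.array([1.0, 1, 1, 10])
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        assert fv.skewness == pytest.approx(m3 / m2**1.5)
        assert fv.skewness == pytest.approx(2 / math.sqrt(3), rel=1e-9)

    def test_peak_averages_below_hot_voxel(self):
        """A single hot voxel is diluted by the 1 cm^3 averaging sphere."""
        grid = VoxelGrid(15, 15, 15, 2.0, 2.0, 2.0)
        v = np.ones(grid.shape)
        v[7, 7, 7] = 100.0
        roi = np.ones(grid.shape, bool)
        fv = intensity_features(_img(grid, v), roi)
        assert 1.0 < fv.peak < 100.0


class TestGlcmFeatures:
    def test_constant_roi_identities(self, grid8):
        roi = np.zeros(grid8.shape, bool)
        roi[2:6, 2:6, 2:6] = True
        f = glcm_features(_img(grid8, np.full(grid8.shape, 250.0)), roi, bin_width=100.0)
        assert f["energy"] == pytest.approx(1.0)
        assert f["joint_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["homogeneity"] == pytest.approx(1.0)

    def test_checkerboard_enumerated_by_hand(self):
        """2x2 checkerboard of levels {1,2}: horizontal/vertical pairs are
        all (1,2)/(2,1) (energy 1/2, entropy 1 bit, correlation -1) while
        both diagonals pair equal levels (energy 1, entropy 0,
        correlation +1); the direction average follows."""
        grid = VoxelGrid(2, 2, 1, 1.0, 1.0, 1.0)
        img = _img(grid, [[[50.0, 150.0], [150.0, 50.0]]])
        f = glcm_features(img, np.ones(grid.shape, bool), bin_width=100.0)
        assert f["energy"] == pytest.approx((0.5 + 0.5 + 1.0 + 1.0) / 4)
        assert f["joint_entropy"] == pytest.approx((1.0 + 1.0 + 0.0 + 0.0) / 4)
        assert f["correlation"] == pytest.approx(0.0, abs=1e-12)
        assert f["joint_average"] == pytest.approx(1.5)

    def test_independent_levels_correlation_near_zero(self):
        grid = VoxelGrid(64, 64, 4, 1.0, 1.0, 1.0)
        rng = np.random.default_rng(42)
        vals = (rng.integers(1, 9, grid.shape) * 100.0) - 50.0
        f = glcm_features(_img(grid, vals), np.ones(grid.shape, bool), bin_width=100.0)
        assert abs(f["correlation"]) < 0.05

    def test_direction_average_permutation_invariant(self, grid8, rng):
        """Energy/entropy bounds hold and features are deterministic."""
        v = rng.random(grid8.shape) * 400
        roi = np.ones(grid8.shape, bool)
        f1 = glcm_features(_img(grid8, v), roi, bin_width=100.0)
        f2 = glcm_features(_img(grid8, v), roi, bin_width=100.0)
        assert f1 == f2
        assert 0 < f1["energy"] <= 1
        assert f1["joint_entropy"] >= 0
        assert 0 < f1["homogeneity"] <= 1
        assert -1 <= f1["correlation"] <= 1

    def test_isolated_voxels_rejected(self):
        grid = VoxelGrid(5, 5, 1, 1.0, 1.0, 1.0)
        roi = np.zeros(grid.shape, bool)
        roi[0, 0, 0] = True
        roi[0, 3, 3] = True  # no distance-1 pair in any direction
        with pytest.raises(ValueError):
            glcm_features(_img(grid, np.ones(grid.shape) * 150), roi, bin_width=100.0)


class TestCompareFeatures:
    def test_identity_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r = compare_features(x, x)
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.pearson_r == pytest.approx(1.0)

    def test_affine_noise_free(self):
        x = np.array([1.0, 2, 3, 4])
        r = compare_features(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.slope_ci[0] <= 2.0 <= r.slope_ci[1]

    def test_r_squared_equals_regression_r2(self, rng):
        x = rng.random(30)
        y = 3 * x + rng.normal(0, 0.3, 30)
        r = compare_features(x, y)
        yhat = r.slope * x + r.intercept
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert r.pearson_r**2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_features(np.ones(5), np.arange(5.0))


class TestNemaRois:
    def test_sphere_mask_volumes_near_analytic(self, nema_desk, desk):
        _, grid = desk
        _, _, spec = nema_desk
        rois = nema_rois(grid, spec)
        vox_ml = grid.voxel_volume_ml
        for d in (22.0, 28.0, 37.0):  # resolvable at this scale
            analytic = 4 / 3 * math.pi * (d / 2) ** 3 / 1000.0
            vol = rois.spheres[d].sum() * vox_ml
            # within one voxel layer of the analytic volume
            surface_layer = 4 * math.pi * (d / 2) ** 2 * grid.dx / 1000.0
            assert abs(vol - analytic) <= surface_layer

    def test_background_excludes_spheres_and_spans_five_slices(self, nema_desk, desk):
        _, grid = desk
        _, _, spec = nema_desk
        rois = nema_rois(grid, spec)
        for m in rois.sphere_masks():
            assert not (rois.background & m).any()
        assert len(np.unique(np.nonzero(rois.background)[0])) == 5

    def test_annulus_into_spheres_rejected(self, nema_desk, desk):
        _, grid = desk
        _, _, spec = nema_desk
        with pytest.raises(ValueError, match="annulus"):
            nema_rois(grid, spec, annulus_inner_mm=40.0, annulus_outer_mm=70.0)
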