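import math
import warnings

import numpy as np
import pytest

from fastpet.geometry import VoxelGrid
from fastpet.phantom import VolumeImage
from fastpet.projection import Sinogram
from fastpet.simulate import (
    SimulationConfig,
    SinogramSet,
    add_noise,
    calibrate_presmooth,
    calibrate_sensitivity,
    denormalize,
    presmooth,
    renormalize,
    simulate_noise_free,
)


def _profile_fwhm(profile, spacing):
    half = profile.max() / 2.0
    i = int(np.argmax(profile))
    left = right = None
    for j in range(1, i + 1):
        if profile[j] >= half and profile[j - 1] < half:
            left = j - 1 + (half - profile[j - 1]) / (profile[j] - profile[j - 1])
            break
    for j in range(i, len(profile) - 1):
        if profile[j] >= half and profile[j + 1] < half:
            right = j + (profile[j] - half) / (profile[j] - profile[j + 1])
            break
    return (right - left) * spacing


@pytest.fixture
def point_source():
    grid = VoxelGrid(41, 41, 41, 1.65, 1.65, 1.646)
    v = np.zeros(grid.shape)
    v[20, 20, 20] = 1.0
    return VolumeImage(v, grid)


class TestPresmooth:
    def test_zero_fwhm_is_identity(self, point_source):
        out = presmooth(point_source, 0.0)
        assert np.array_equal(out.values, point_source.values)

    def test_impulse_response_fwhm_is_three_mm(self, point_source):
        """Default 3 mm kernel measured on the printed 1.65 mm grid."""
        out = presmooth(point_source, 3.0)
        fwhm = _profile_fwhm(out.values[20, 20, :], point_source.grid.dx)
        assert fwhm == pytest.approx(3.0, abs=0.2)

    def test_total_conserved(self, point_source):
        out = presmooth(point_source, 5.0)
        assert abs(out.total - point_source.total) / point_source.total < 1e-6

    def test_isotropy_on_anisotropic_grid(self, point_source):
        out = presmooth(point_source, 4.0)
        fx = _profile_fwhm(out.values[20, 20, :], 1.65)
        fz = _profile_fwhm(out.values[:, 20, 20], 1.646)
        assert fx == pytest.approx(fz, abs=0.2)


@pytest.fixture(scope="module")
def source(mini):
    """100 kBq distributed source, no attenuation."""
    _, grid = mini
    v = np.zeros(grid.shape)
    v[1:3, 10:22, 10:22] = 1.0
    v *= 100_000.0 / (v.sum() * grid.voxel_volume_ml)  # total 100 kBq
    act = VolumeImage(v, grid)
    mu = VolumeImage(np.zeros(grid.shape), grid, "attenuation")
    return act, mu


class TestNoiseFreeSimulation:
    def test_sensitivity_contract_exact(self, mini, source):
        """Non-attenuated 100 kBq source, T=10 s -> exactly 38 cps/kBq."""
        g, _ = mini
        act, mu = source
        cfg = SimulationConfig(acquisition_time_s=10.0, scatter="off")
        sim = simulate_noise_free(act, mu, g, cfg)
        cps_per_kbq = sim.counts["trues"] / (100.0 * 10.0)
        assert cps_per_kbq == pytest.approx(38.0, rel=1e-9)

    def test_random_rate_exact(self, mini, source):
        g, _ = mini
        act, mu = source
        cfg = SimulationConfig(acquisition_time_s=5.0, scatter="off")
        sim = simulate_noise_free(act, mu, g, cfg)
        assert sim.counts["randoms"] / sim.counts["trues"] == pytest.approx(0.20, abs=1e-12)

    def test_zero_activity_gives_zero_sinograms(self, mini):
        g, grid = mini
        act = VolumeImage(np.zeros(grid.shape), grid)
        mu = VolumeImage(np.zeros(grid.shape), grid, "attenuation")
        sim = simulate_noise_free(act, mu, g, SimulationConfig(acquisition_time_s=1.0))
        assert sim.trues.total == sim.scatter.total == sim.randoms.total == 0.0

    def test_linearity_in_time_and_sensitivity(self, mini, source):
        g, _ = mini
        act, mu = source
        base = simulate_noise_free(
            act, mu, g, SimulationConfig(acquisition_time_s=2.0, scatter="off")
        )
        t4 = simulate_noise_free(
            act, mu, g, SimulationConfig(acquisition_time_s=8.0, scatter="off")
        )
        s2 = simulate_noise_free(
            act,
            mu,
            g,
            SimulationConfig(acquisition_time_s=2.0, sensitivity_cps_per_kbq=76.0, scatter="off"),
        )
        assert t4.counts["trues"] == pytest.approx(4 * base.counts["trues"], rel=1e-12)
        assert s2.counts["trues"] == pytest.approx(2 * base.counts["trues"], rel=1e-12)

    def test_prompts_are_sum_of_components(self, mini, source):
        g, _ = mini
        act, mu = source
        sim = simulate_noise_free(act, mu, g, SimulationConfig(acquisition_time_s=1.0))
        assert np.array_equal(
            sim.prompts_noise_free,
            sim.trues.values + sim.scatter.values + sim.randoms.values,
        )

    def test_tof_delayed_window_total(self, mini, source):
        """With TOF on, the delayed bin integrates randoms over TOF exactly."""
        g, _ = mini
        act, mu = source
        cfg = SimulationConfig(acquisition_time_s=3.0, scatter="off", tof=True)
        sim = simulate_noise_free(act, mu, g, cfg)
        assert sim.trues.values.ndim == 4
        assert sim.delayed_noise_free.sum() == pytest.approx(
            0.20 * sim.counts["trues"], rel=1e-9
        )

    def test_grid_mismatch_rejected(self, mini, source):
        g, grid = mini
        act, _ = source
        other = VoxelGrid(16, 16, 4, 10.0, 10.0, 5.0)
        mu2 = VolumeImage(np.zeros(other.shape), other, "attenuation")
        with pytest.raises(ValueError):
            simulate_noise_free(act, mu2, g, SimulationConfig(acquisition_time_s=1.0))

    def test_invalid_time_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(acquisition_time_s=0.0)


class TestDenormalize:
    def test_uniform_is_identity(self, mini, rng):
        g, _ = mini
        s = Sinogram(rng.random(g.sinogram_shape()), g)
        assert np.array_equal(denormalize(s, "uniform").values, s.values)

    def test_constant_normalization_divides(self, mini, rng):
        g, _ = mini
        s = Sinogram(rng.random(g.sinogram_shape()), g)
        norm = np.full(g.sinogram_shape(), 2.0)
        assert np.allclose(denormalize(s, norm).values, s.values / 2.0)

    def test_round_trip_with_renormalize(self, mini, rng):
        g, _ = mini
        s = Sinogram(rng.random(g.sinogram_shape()) + 0.5, g)
        norm = rng.random(g.sinogram_shape()) + 0.5
        back = renormalize(denormalize(s, norm), norm)
        assert np.abs(back.values - s.values).max() < 1e-6 * s.values.max()

    def test_zero_bins_rejected(self, mini, rng):
        g, _ = mini
        s = Sinogram(rng.random(g.sinogram_shape()), g)
        norm = np.ones(g.sinogram_shape())
        norm[0, 0, 0] = 0.0
        with pytest.raises(ValueError):
            denormalize(s, norm)


@pytest.fixture(scope="module")
def noise_base(mini):
    g, grid = mini
    rng = np.random.default_rng(99)
    trues = Sinogram(50.0 * rng.random(g.sinogram_shape()), g)
    zero = Sinogram(np.zeros(g.sinogram_shape()), g)
    randoms = Sinogram(np.full(g.sinogram_shape(), 5.0), g)
    return SinogramSet(trues=trues, scatter=zero, randoms=randoms)


class TestAddNoise:
    def test_same_seed_bit_identical(self, mini, noise_base):
        g, _ = mini
        cfg = SimulationConfig(acquisition_time_s=1.0, seed=7, n_realizations=2)
        a = add_noise(noise_base, g, cfg)
        p0 = a.prompts_noisy[0].copy()
        b = add_noise(noise_base, g, cfg)
        assert np.array_equal(p0, b.prompts_noisy[0])
        assert not np.array_equal(b.prompts_noisy[0], b.prompts_noisy[1])

    def test_poisson_mean(self, mini, noise_base):
        """Mean of total counts over 200 realizations within 3 SE."""
        g, _ = mini
        cfg = SimulationConfig(acquisition_time_s=1.0, seed=11, n_realizations=200)
        out = add_noise(noise_base, g, cfg)
        totals = np.array([p.sum() for p in out.prompts_noisy])
        expected = out.prompts_noise_free.sum()
        se = math.sqrt(expected / 200)
        assert abs(totals.mean() - expected) < 3 * se

    def test_poisson_dispersion_index(self, mini, noise_base):
        """Per-bin variance/mean in [0.9, 1.1] for bins with mean > 10."""
        g, _ = mini
        cfg = SimulationConfig(acquisition_time_s=1.0, seed=13, n_realizations=200)
        out = add_noise(noise_base, g, cfg)
        arr = np.stack(out.prompts_noisy)
        m, v = arr.mean(axis=0), arr.var(axis=0)
        sel = m > 10
        assert 0.9 < (v[sel] / m[sel]).mean() < 1.1

    def test_negative_noise_free_rejected(self, mini):
        g, _ = mini
        bad = Sinogram(np.zeros(g.sinogram_shape()), g, tof=False)
        bad.values[0, 0, 0] = -1.0
        ss = SinogramSet(trues=bad, scatter=bad.copy_with(np.zeros_like(bad.values)),
                         randoms=bad.copy_with(np.zeros_like(bad.values)))
        with pytest.raises(ValueError):
            add_noise(ss, g, SimulationConfig(acquisition_time_s=1.0))


class TestCalibration:
    def test_sensitivity_round_trip(self, desk, nema_desk):
        g, _ = desk
        act, att, _ = nema_desk
        cfg = SimulationConfig(acquisition_time_s=10.0, scatter="off")
        sim = simulate_noise_free(act, att, g, cfg)
        s = calibrate_sensitivity(sim.counts["trues"], act, att, g, cfg)
        assert s == pytest.approx(38.0, rel=1e-9)

    def test_doubling_counts_doubles_sensitivity(self, desk, nema_desk):
        g, _ = desk
        act, att, _ = nema_desk
        cfg = SimulationConfig(acquisition_time_s=10.0, scatter="off")
        sim = simulate_noise_free(act, att, g, cfg)
        s1 = calibrate_sensitivity(sim.counts["trues"], act, att, g, cfg)
        s2 = calibrate_sensitivity(2 * sim.counts["trues"], act, att, g, cfg)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_time_invariance(self, desk, nema_desk):
        """S recovered from a long scan equals S from a short scan."""
        g, _ = desk
        act, att, _ = nema_desk
        c10 = SimulationConfig(acquisition_time_s=600.0, scatter="off")
        c1 = SimulationConfig(acquisition_time_s=60.0, scatter="off")
        obs10 = simulate_noise_free(act, att, g, c10).counts["trues"]
        obs1 = simulate_noise_free(act, att, g, c1).counts["trues"]
        assert calibrate_sensitivity(obs10, act, att, g, c10) == pytest.approx(
            calibrate_sensitivity(obs1, act, att, g, c1), rel=1e-12
        )

    def test_invalid_observed_counts(self, desk, nema_desk):
        g, _ = desk
        act, att, _ = nema_desk
        with pytest.raises(ValueError):
            calibrate_sensitivity(0.0, act, att, g, SimulationConfig(acquisition_time_s=1.0))


@pytest.fixture(scope="module")
def presmooth_context(desk, nema_desk):
    from fastpet.evaluate import nema_rois, recovery_coefficient
    from fastpet.projection import attenuation_factors
    from fastpet.recon import ReconConfig, op_osem
    from fastpet.simulate import counts_to_activity

    g, grid = desk
    act, att, spec = nema_desk
    rcfg = ReconConfig(n_iterations=4, n_subsets=5, grid=grid)
    cfg = SimulationConfig(acquisition_time_s=10.0, scatter="off", presmooth_fwhm_mm=3.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = simulate_noise_free(act, att, g, cfg)
        img = op_osem(
            Sinogram(sim.prompts_noise_free, g),
            sim.randoms,
            sim.scatter,
            attenuation_factors(att, g),
            g,
            rcfg,
        )
        a = counts_to_activity(img, cfg)
        rois = nema_rois(grid, spec)
        ref_rc = [recovery_coefficient(a, m, 27369.0) for m in rois.sphere_masks()]
    return g, act, att, spec, cfg, rcfg, ref_rc


class TestPresmoothCalibration:
    def test_recovers_generating_fwhm(self, presmooth_context):
        g, act, att, spec, cfg, rcfg, ref_rc = presmooth_context
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, table = calibrate_presmooth(
                ref_rc, [1.0, 3.0, 5.0], act, att, spec, g, cfg, rcfg
            )
        assert best == 3.0
        assert table[3.0] == pytest.approx(0.0, abs=1e-15)
        assert set(table) == {1.0, 3.0, 5.0}  # objective reported per candidate

    def test_single_candidate_returned(self, presmooth_context):
        g, act, att, spec, cfg, rcfg, ref_rc = presmooth_context
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, table = calibrate_presmooth(ref_rc, [2.5], act, att, spec, g, cfg, rcfg)
        assert best == 2.5 and len(table) == 1

    def test_empty_grid_rejected(self, presmooth_context):
        g, act, att, spec, cfg, rcfg, ref_rc = presmooth_context
        with pytest.raises(ValueError):
            calibrate_presmooth(ref_rc, [], act, att, spec, g, cfg, rcfg)
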