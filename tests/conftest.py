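"""Shared fixtures.

Heavy end-to-end artifacts (desk-scale NEMA phantom, trend report,
concordance report, RC-bias run) are session-scoped so the expensive
simulate+reconstruct work happens once per test run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from fastpet.geometry import ScannerGeometry, VoxelGrid, make_scaled_geometry
from fastpet.phantom import make_nema_iq

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def desk():
    """Scale-0.25 Vision-600 variant: grid 110 x 110 x 40, 13 views."""
    return make_scaled_geometry(0.25)


@pytest.fixture(scope="session")
def nema_desk(desk):
    g, grid = desk
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 10 mm sphere is sub-voxel at this scale
        act, att, spec = make_nema_iq(grid)
    return act, att, spec


@pytest.fixture(scope="session")
def mini():
    """Tiny single-ring geometry for fast projector / EM tests."""
    g = ScannerGeometry(
        name="mini",
        ring_radius_mm=200.0,
        n_projections=48,
        n_views=24,
        n_planes=4,
        span=1,
        n_tof_bins=5,
        tof_bin_width_ps=400.0,
        timing_resolution_ps=500.0,
        fov_transaxial_mm=160.0,
        fov_axial_mm=20.0,
    )
    grid = VoxelGrid(nx=32, ny=32, nz=4, dx=5.0, dy=5.0, dz=5.0)
    return g, grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240806)


@pytest.fixture(scope="session")
def nema_trend_report():
    """Five count levels x two realizations at desk scale (shared)."""
    from fastpet.experiments import NemaConfig, run_nema_experiment

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_nema_experiment(
            NemaConfig(times_s=(5.0, 10.0, 30.0, 60.0, 120.0), n_realizations=2, seed=3)
        )


@pytest.fixture(scope="session")
def rc_bias_result():
    """Desk-scale 120 s RC-bias run: 5 noisy realizations vs noise-free."""
    from fastpet.experiments import nema_rc_bias

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nema_rc_bias(seed=1, scale=0.25, time_s=120.0, n_realizations=5)


@pytest.fixture(scope="session")
def concordance_report():
    from fastpet.experiments import ConcordanceConfig, run_concordance_experiment

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_concordance_experiment(ConcordanceConfig(seed=4))
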