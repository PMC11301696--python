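"""Single-scatter simulation (SSS) and inverse single-slice rebinning.

The scatter sinogram is estimated slice by slice in 2D: for every LOR
and every scatter point P (a deterministic sub-sample of voxels with
non-negligible attenuation) the single-scatter contribution is

    emission integral along one detector leg
    x attenuation survival along both legs
    x mu(P)                       (scatter probability density at P)
    x Klein-Nishina cross-section at the scattering angle
    x energy-window acceptance of the scattered photon
    x inverse-square solid-angle factors of both legs,

summed over the two emission-leg assignments and all points, then
smoothed with a small Gaussian in sinogram space.  The per-slice 2D
estimates are expanded to the full 3D plane stack by inverse
single-slice rebinning (linear interpolation between the two nearest
slice positions).

Absolute scaling of the scatter estimate against detector efficiencies
(as vendor software does) is not reproducible without detector data;
:func:`scale_scatter` therefore scales the estimate to a configurable
scatter fraction of the prompts instead, with an "absolute" passthrough
mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import ScannerGeometry
from .phantom import VolumeImage
from .projection import Sinogram, axial_interp_matrix

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: 511 keV annihilation photon energy
_E0_KEV = 511.0
#: attenuation threshold (cm^-1) below which a voxel cannot scatter
_MU_FLOOR = 0.005


@dataclass(frozen=True)
class ScatterConfig:
    """Settings of the single-scatter estimate.

    ``scatter_fraction_target`` is either a fraction in (0, 1) -- the
    estimate is rescaled so scatter / (scatter + trues) hits it exactly
    -- or the string ``"absolute"`` to keep the model's raw scale.
    The default 435-585 keV energy window is a typical Vision setting.
    """

    n_scatter_points: int = 500
    energy_window_keV: tuple[float, float] = (435.0, 585.0)
    scatter_fraction_target: float | str = 0.30
    smoothing_fwhm_bins: float = 3.0
    n_detector_samples: int = 0      # 0 = auto (4 * n_views)
    n_path_samples: int = 64

    def __post_init__(self) -> None:
        if self.n_scatter_points < 1:
            raise ValueError("n_scatter_points must be >= 1")
        lo, hi = self.energy_window_keV
        if not (0 < lo < hi):
            raise ValueError("energy window must satisfy 0 < low < high")
        if not isinstance(self.scatter_fraction_target, str):
            f = float(self.scatter_fraction_target)
            if not (0 < f < 1):
                raise ValueError("fractional scatter target must lie in (0, 1)")
        if self.smoothing_fwhm_bins < 0:
            raise ValueError("smoothing_fwhm_bins must be >= 0")


def _klein_nishina(cos_theta: np.ndarray) -> np.ndarray:
    """Unnormalized Klein-Nishina differential cross-section at 511 keV."""
    k = 1.0 / (2.0 - cos_theta)          # E'/E for E = m_e c^2
    sin2 = 1.0 - cos_theta**2
    return k * k * (k + 1.0 / k - sin2)


def scattered_energy_keV(cos_theta: np.ndarray) -> np.ndarray:
    """Compton-scattered photon energy for a 511 keV primary."""
    return _E0_KEV / (2.0 - cos_theta)


def estimate_scatter_2d(
    activity: VolumeImage,
    mu: VolumeImage,
    g: ScannerGeometry,
    cfg: ScatterConfig,
    slice_index: int,
) -> np.ndarray:
    """2D single-scatter sinogram (n_views x n_projections) for one slice."""
    if activity.grid != mu.grid:
        raise ValueError("activity and attenuation must share a grid")
    grid = activity.grid
    if not (0 <= slice_index < grid.nz):
        raise IndexError(f"slice {slice_index} outside [0, {grid.nz})")
    act2d = np.asarray(activity.values[slice_index], dtype=np.float64)
    mu2d = np.asarray(mu.values[slice_index], dtype=np.float64)
    out = np.zeros((g.n_views, g.n_projections))
    if not np.any(mu2d > _MU_FLOOR) or not np.any(act2d > 0):
        return out

    xs, ys, _ = grid.axis_centers()

    # deterministic scatter-point sub-grid: every k-th attenuating voxel
    cand = np.flatnonzero((mu2d > _MU_FLOOR).ravel())
    stride = max(1, int(math.ceil(cand.size / cfg.n_scatter_points)))
    pts = cand[::stride]
    iy, ix = np.unravel_index(pts, mu2d.shape)
    P = np.stack([xs[ix], ys[iy]], axis=1)              # (n_p, 2) mm
    mu_P = mu2d[iy, ix]
    n_p = P.shape[0]

    # detector ring samples and per-(point, detector) leg integrals
    n_det = cfg.n_detector_samples or 4 * g.n_views
    alpha = (np.arange(n_det) + 0.5) * (2 * math.pi / n_det)
    D = g.ring_radius_mm * np.stack([np.cos(alpha), np.sin(alpha)], axis=1)  # (n_det, 2)

    n_samp = cfg.n_path_samples
    frac = (np.arange(n_samp) + 0.5) / n_samp
    # sample points along each P -> D segment: (n_p, n_det, n_samp, 2)
    seg = P[:, None, None, :] + frac[None, None, :, None] * (
        D[None, :, None, :] - P[:, None, None, :]
    )
    cx = (seg[..., 0] - grid.origin[0]) / grid.dx
    cy = (seg[..., 1] - grid.origin[1]) / grid.dy
    coords = np.stack([cy.ravel(), cx.ravel()])
    act_samp = map_coordinates(act2d, coords, order=1, mode="constant").reshape(
        n_p, n_det, n_samp
    )
    mu_samp = map_coordinates(mu2d, coords, order=1, mode="constant").reshape(
        n_p, n_det, n_samp
    )
    seg_len = np.linalg.norm(D[None, :, :] - P[:, None, :], axis=2)  # (n_p, n_det) mm
    a_leg = act_samp.mean(axis=2) * seg_len                           # emission integrals
    m_leg = mu_samp.mean(axis=2) * seg_len * 0.1                      # optical depth (mu in cm^-1)

    # enumerate LORs and their detector-ring endpoints
    s = g.radial_offsets_mm()
    phi = g.view_angles()
    S, PHI = np.meshgrid(s, phi)                                      # (n_views, n_s)
    S, PHI = S.ravel(), PHI.ravel()
    inside = np.abs(S) < g.ring_radius_mm - 1e-9
    te = np.zeros_like(S)
    te[inside] = np.sqrt(g.ring_radius_mm**2 - S[inside] ** 2)
    nvec = np.stack([np.cos(PHI), np.sin(PHI)], axis=1)
    uvec = np.stack([-np.sin(PHI), np.cos(PHI)], axis=1)
    D1 = S[:, None] * nvec + te[:, None] * uvec                        # (n_lor, 2)
    D2 = S[:, None] * nvec - te[:, None] * uvec

    def interp_leg(table: np.ndarray, endpoints: np.ndarray) -> np.ndarray:
        """Interpolate per-point leg integrals over the detector angle."""
        ang = np.mod(np.arctan2(endpoints[:, 1], endpoints[:, 0]), 2 * math.pi)
        fidx = ang / (2 * math.pi) * n_det - 0.5
        i0 = np.floor(fidx).astype(np.int64)
        w1 = fidx - i0
        i0 = np.mod(i0, n_det)
        i1 = np.mod(i0 + 1, n_det)
        return table[:, i0] * (1.0 - w1)[None, :] + table[:, i1] * w1[None, :]

    a1 = interp_leg(a_leg, D1)            # (n_p, n_lor)
    a2 = interp_leg(a_leg, D2)
    m1 = interp_leg(m_leg, D1)
    m2 = interp_leg(m_leg, D2)

    v1 = P[:, None, :] - D1[None, :, :]   # D1 -> P
    v2 = D2[None, :, :] - P[:, None, :]   # P -> D2
    d1 = np.linalg.norm(v1, axis=2)
    d2 = np.linalg.norm(v2, axis=2)
    denom = d1 * d2
    denom[denom == 0] = np.inf
    cos_t = (v1 * v2).sum(axis=2) / denom
    cos_t = np.clip(cos_t, -1.0, 1.0)

    kn = _klein_nishina(cos_t)
    e_scat = scattered_energy_keV(cos_t)
    lo, hi = cfg.energy_window_keV
    accept = (e_scat >= lo) & (e_scat <= hi)
    geom = 1.0 / np.maximum(d1 * d1 * d2 * d2, 1.0)
    contrib = (
        mu_P[:, None]
        * (a1 + a2)
        * np.exp(-(m1 + m2))
        * kn
        * accept
        * geom
    )
    prof = contrib.sum(axis=0)
    prof[~inside] = 0.0
    out = prof.reshape(g.n_views, g.n_projections)

    if cfg.smoothing_fwhm_bins > 0:
        out = gaussian_filter(out, sigma=cfg.smoothing_fwhm_bins / _FWHM_TO_SIGMA, mode="nearest")
    return np.maximum(out, 0.0)


def inverse_ssrb(slices: np.ndarray, g: ScannerGeometry) -> Sinogram:
    """Expand per-slice 2D scatter sinograms to the 3D plane stack.

    ``slices`` has shape (n_slices, n_views, n_projections), one entry
    per image slice, assumed uniformly spaced over the axial FOV.  Each
    of the ``g.n_planes`` planes receives the linear interpolation of
    the two nearest slice estimates.
    """
    slices = np.asarray(slices, dtype=np.float64)
    if slices.ndim != 3 or slices.shape[0] == 0:
        raise ValueError("expected a non-empty (n_slices, n_views, n_projections) stack")
    if slices.shape[1:] != (g.n_views, g.n_projections):
        raise ValueError(
            f"slice sinograms {slices.shape[1:]} do not match geometry "
            f"({g.n_views}, {g.n_projections})"
        )
    nz = slices.shape[0]
    dz = g.fov_axial_mm / nz
    slice_z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    L = axial_interp_matrix(g, slice_z)
    out = (L @ slices.reshape(nz, -1)).reshape(g.n_planes, g.n_views, g.n_projections)
    return Sinogram(out, g, tof=False)


def scale_scatter(scatter: Sinogram, trues: Sinogram, cfg: ScatterConfig) -> Sinogram:
    """Scale the scatter estimate to the configured scatter fraction.

    With a fractional target f, one global factor is applied so that
    sum(scatter) / (sum(scatter) + sum(trues)) == f exactly; with
    ``"absolute"`` the estimate is returned unchanged.
    """
    if isinstance(cfg.scatter_fraction_target, str):
        if cfg.scatter_fraction_target != "absolute":
            raise ValueError(f"unknown scatter target {cfg.scatter_fraction_target!r}")
        return scatter
    f = float(cfg.scatter_fraction_target)
    if not (0 < f < 1):
        raise ValueError("scatter fraction target must lie in (0, 1)")
    s_tot = scatter.total
    t_tot = trues.total
    if s_tot == 0:
        if t_tot == 0:
            return scatter
        raise ValueError("cannot scale an all-zero scatter estimate to a nonzero fraction")
    k = f / (1.0 - f) * t_tot / s_tot
    return scatter.copy_with(scatter.values * k)
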