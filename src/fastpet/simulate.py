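"""Analytical simulation pipeline: activity map -> noisy prompt sinograms.

The pipeline mirrors a clinical acquisition chain step by step:

1.  pre-smoothing of the activity map with a 3D isotropic Gaussian
    (intrinsic resolution: positron range, non-collinearity, detector),
2.  conversion Bq/ml -> decays per voxel (x voxel volume in ml x T),
3.  counts-preserving Joseph forward projection (optionally TOF),
4.  attenuation by the survival-factor sinogram,
5.  scanner sensitivity S (cps/kBq): trues = S/1000 x attenuated
    projection, so a non-attenuated source yields exactly S*T counts
    per kBq,
6.  uniform randoms scaled to ``random_rate x trues``,
7.  single-scatter estimate expanded by inverse SSRB and scaled to the
    configured scatter fraction,
8.  denormalization (identity under the uniform-normalization model),
9.  noise-free prompts = trues + scatter + randoms; the delayed-window
    bin is the randoms summed over the TOF dimension,
10. independent Poisson realizations of prompts and delayed window.

Calibration helpers recover the sensitivity from an observed true-count
total (closed form -- counts are linear in S) and the pre-smoothing
FWHM by grid search against reference sphere recovery coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import ScannerGeometry
from .phantom import PhantomSpec, VolumeImage
from .projection import Sinogram, attenuation_factors, get_plan
from .scatter import ScatterConfig, estimate_scatter_2d, inverse_ssrb, scale_scatter

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and calibration settings.

    Defaults are the NEMA-calibrated values: sensitivity 38 cps/kBq,
    random rate 20% of trues, 3 mm pre-smoothing FWHM.
    """

    acquisition_time_s: float
    sensitivity_cps_per_kbq: float = 38.0
    random_rate: float = 0.20
    presmooth_fwhm_mm: float = 3.0
    tof: bool = False
    scatter: ScatterConfig | Literal["off"] | None = "off"
    normalization: np.ndarray | Literal["uniform"] = "uniform"
    seed: int = 0
    n_realizations: int = 1

    def __post_init__(self) -> None:
        if self.acquisition_time_s <= 0:
            raise ValueError("acquisition time must be > 0")
        if self.sensitivity_cps_per_kbq <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.random_rate < 0:
            raise ValueError("random rate must be >= 0")
        if self.presmooth_fwhm_mm < 0:
            raise ValueError("pre-smoothing FWHM must be >= 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass
class SinogramSet:
    """Noise-free components plus per-realization noisy sinograms."""

    trues: Sinogram
    scatter: Sinogram
    randoms: Sinogram
    prompts_noisy: list[np.ndarray] = field(default_factory=list)
    delayed_noisy: list[np.ndarray] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def prompts_noise_free(self) -> np.ndarray:
        return self.trues.values + self.scatter.values + self.randoms.values

    @property
    def delayed_noise_free(self) -> np.ndarray:
        if self.trues.tof:
            return self.randoms.values.sum(axis=-1)
        return self.randoms.values


def presmooth(activity: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """3D isotropic Gaussian smoothing; total activity is conserved.

    sigma = fwhm / 2.3548, expressed per axis in voxel units from the
    grid spacings.  The result is globally renormalized so that edge
    truncation cannot leak counts.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return activity.copy_with(activity.values.copy())
    sigma_mm = fwhm_mm / _FWHM_TO_SIGMA
    g = activity.grid
    sigma_vox = (sigma_mm / g.dz, sigma_mm / g.dy, sigma_mm / g.dx)
    out = gaussian_filter(np.asarray(activity.values, np.float64), sigma_vox, mode="constant")
    total_in = activity.values.sum()
    total_out = out.sum()
    if total_out > 0:
        out *= total_in / total_out
    return activity.copy_with(out)


def _uniform_like(template: np.ndarray, total: float) -> np.ndarray:
    return np.full_like(template, total / template.size)


def simulate_noise_free(
    activity: VolumeImage,
    mu: VolumeImage,
    g: ScannerGeometry,
    cfg: SimulationConfig,
) -> SinogramSet:
    """Steps 1-8: noise-free trues / scatter / randoms sinograms."""
    if activity.grid != mu.grid:
        raise ValueError("activity and attenuation maps must share a grid")
    grid = activity.grid
    T = cfg.acquisition_time_s

    act_s = presmooth(activity, cfg.presmooth_fwhm_mm)
    decays = act_s.values * grid.voxel_volume_ml * T  # decays per voxel

    plan = get_plan(g, grid)
    proj = plan.forward(decays, tof=cfg.tof)
    attn = attenuation_factors(mu, g)
    attn_v = attn.values[..., None] if cfg.tof else attn.values
    s_per_decay = cfg.sensitivity_cps_per_kbq / 1000.0
    trues_v = s_per_decay * proj * attn_v
    trues = Sinogram(trues_v, g, tof=cfg.tof)

    randoms = Sinogram(
        _uniform_like(trues_v, cfg.random_rate * trues.total), g, tof=cfg.tof
    )

    if cfg.scatter in (None, "off"):
        scatter = Sinogram(np.zeros_like(trues_v), g, tof=cfg.tof)
    else:
        scfg: ScatterConfig = cfg.scatter
        stack = np.stack(
            [
                estimate_scatter_2d(act_s, mu, g, scfg, k)
                for k in range(grid.nz)
            ]
        )
        scatter3d = scale_scatter(inverse_ssrb(stack, g), _as_non_tof(trues), scfg)
        sval = scatter3d.values
        if cfg.tof:  # spread uniformly across TOF bins (sums back correctly)
            sval = np.repeat(sval[..., None], g.n_tof_bins, axis=-1) / g.n_tof_bins
        scatter = Sinogram(sval, g, tof=cfg.tof)

    trues = denormalize(trues, cfg.normalization)
    scatter = denormalize(scatter, cfg.normalization)
    randoms = denormalize(randoms, cfg.normalization)

    out = SinogramSet(trues=trues, scatter=scatter, randoms=randoms)
    out.counts["trues"] = trues.total
    out.counts["scatter"] = scatter.total
    out.counts["randoms"] = randoms.total
    return out


def _as_non_tof(s: Sinogram) -> Sinogram:
    if not s.tof:
        return s
    return Sinogram(s.values.sum(axis=-1), s.geometry, tof=False)


def denormalize(s: Sinogram, normalization) -> Sinogram:
    """Bin-wise division by the normalization sinogram (identity if uniform)."""
    if isinstance(normalization, str):
        if normalization != "uniform":
            raise ValueError(f"unknown normalization {normalization!r}")
        return s
    norm = np.asarray(normalization, dtype=np.float64)
    if s.tof and norm.ndim == s.values.ndim - 1:
        norm = norm[..., None]
    if np.broadcast_shapes(norm.shape, s.values.shape) != s.values.shape:
        raise ValueError("normalization sinogram shape mismatch")
    if np.any(norm == 0):
        raise ValueError("normalization sinogram contains zero bins")
    return s.copy_with(s.values / norm)


def renormalize(s: Sinogram, normalization) -> Sinogram:
    """Inverse of :func:`denormalize` (reconstruction-side multiplication)."""
    if isinstance(normalization, str):
        return s
    norm = np.asarray(normalization, dtype=np.float64)
    if s.tof and norm.ndim == s.values.ndim - 1:
        norm = norm[..., None]
    return s.copy_with(s.values * norm)


def add_noise(sset: SinogramSet, g: ScannerGeometry, cfg: SimulationConfig) -> SinogramSet:
    """Steps 9-10: Poisson realizations of prompts and the delayed window.

    Realization i uses the independent stream ``seed + i``; the delayed
    window is sampled independently of the noisy prompts, as a physical
    delayed-window acquisition would be.
    """
    nf_prompts = sset.prompts_noise_free
    nf_delayed = sset.delayed_noise_free
    if np.any(nf_prompts < 0) or np.any(nf_delayed < 0):
        raise ValueError("noise-free sinograms must be non-negative")
    sset.prompts_noisy = []
    sset.delayed_noisy = []
    sset.counts.setdefault("prompts_noisy", [])
    sset.counts["prompts_noisy"] = []
    for i in range(cfg.n_realizations):
        rng = np.random.default_rng(cfg.seed + i)
        p = rng.poisson(nf_prompts).astype(np.float64)
        d = rng.poisson(nf_delayed).astype(np.float64)
        sset.prompts_noisy.append(p)
        sset.delayed_noisy.append(d)
        sset.counts["prompts_noisy"].append(float(p.sum()))
    return sset


def simulate(
    activity: VolumeImage,
    mu: VolumeImage,
    g: ScannerGeometry,
    cfg: SimulationConfig,
) -> SinogramSet:
    """Full steps 1-10: noise-free components plus noisy realizations."""
    sset = simulate_noise_free(activity, mu, g, cfg)
    return add_noise(sset, g, cfg)


def counts_to_activity(img: VolumeImage, cfg: SimulationConfig) -> VolumeImage:
    """Convert a reconstructed counts-domain image back to Bq/ml.

    The reconstruction model works in emission counts per voxel; with
    sensitivity S (cps/kBq) and acquisition time T the conversion is
    activity = counts * 1000 / (S * voxel_ml * T).
    """
    scale = 1000.0 / (
        cfg.sensitivity_cps_per_kbq * img.grid.voxel_volume_ml * cfg.acquisition_time_s
    )
    return VolumeImage(img.values * scale, img.grid, quantity="reconstructed")


def calibrate_sensitivity(
    observed_true_counts: float,
    activity: VolumeImage,
    mu: VolumeImage,
    g: ScannerGeometry,
    cfg: SimulationConfig,
) -> float:
    """Sensitivity S (cps/kBq) aligning simulated with observed true counts.

    True counts are exactly linear in S, so a single noise-free run at
    the configured S suffices: S* = S x observed / simulated.
    """
    if observed_true_counts <= 0:
        raise ValueError("observed true counts must be > 0")
    base = replace(cfg, scatter="off")
    sim = simulate_noise_free(activity, mu, g, base)
    t = sim.counts["trues"]
    if t <= 0:
        raise ValueError("simulated true counts are zero (attenuated projection empty)")
    return cfg.sensitivity_cps_per_kbq * observed_true_counts / t


def calibrate_presmooth(
    reference_rc_per_sphere: Sequence[float],
    fwhm_grid_mm: Sequence[float],
    activity: VolumeImage,
    mu: VolumeImage,
    spec: PhantomSpec,
    g: ScannerGeometry,
    cfg: SimulationConfig,
    recon_cfg=None,
) -> tuple[float, dict[float, float]]:
    """Grid search on the pre-smoothing FWHM against reference sphere RCs.

    For every candidate FWHM the phantom is simulated noise-free,
    reconstructed, and the sphere recovery coefficients compared to the
    reference; the candidate minimizing the summed squared RC
    difference is returned together with the full objective table
    (audit trail).  Deterministic: no Poisson noise is drawn.
    """
    from .evaluate import nema_rois, recovery_coefficient
    from .recon import ReconConfig, op_osem

    fwhms = list(fwhm_grid_mm)
    if not fwhms:
        raise ValueError("empty FWHM grid")
    ref = np.asarray(reference_rc_per_sphere, dtype=np.float64)
    if np.any(ref <= 0) or np.any(ref > 1.5):
        raise ValueError("reference RCs must lie in (0, 1.5]")
    if recon_cfg is None:
        recon_cfg = ReconConfig(n_iterations=8, n_subsets=5, grid=activity.grid)
    rois = nema_rois(activity.grid, spec)
    sphere_conc = max(s.activity for s in spec.spheres())

    objective: dict[float, float] = {}
    for fwhm in fwhms:
        c = replace(cfg, presmooth_fwhm_mm=float(fwhm), n_realizations=1)
        sim = simulate_noise_free(activity, mu, g, c)
        attn = attenuation_factors(mu, g)
        recon = op_osem(
            Sinogram(sim.prompts_noise_free, g, tof=c.tof),
            sim.randoms,
            sim.scatter,
            attn,
            g,
            recon_cfg,
        )
        act_img = counts_to_activity(recon, c)
        rcs = np.array(
            [
                recovery_coefficient(act_img, m, sphere_conc)
                for m in rois.sphere_masks()
            ]
        )
        objective[float(fwhm)] = float(((rcs - ref) ** 2).sum())
    best = min(objective, key=objective.get)
    return best, objective
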