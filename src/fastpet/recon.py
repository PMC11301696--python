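"""Ordinary-Poisson OSEM reconstruction.

The forward model for subset u is

    y_u = attn_u * F_u(G x) + randoms_u + scatter_u

with F the counts-preserving Joseph projector restricted to the
subset's views, G an optional isotropic image-space PSF Gaussian and
attn the attenuation-factor sinogram.  The multiplicative update

    x <- (x / s_u) * A_u^T( p_u / (A_u x + r_u + s̄_u) ),
    s_u = A_u^T 1

is the classic EM step; with a single subset the Poisson log-likelihood
is non-decreasing, which the test-suite uses as the correctness oracle
(the projector pair is an exact matrix transpose, so the guarantee
holds to numerical precision).

Subsets are view-interleaved (view j belongs to subset j mod
n_subsets).  Unbalanced subset sizes are accepted -- each subset uses
its own sensitivity image -- with a warning, so the printed clinical
protocols (5 subsets) remain usable on scaled geometries whose view
count is not a multiple of 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import ScannerGeometry, VoxelGrid
from .phantom import VolumeImage
from .projection import Sinogram, get_plan

_FWHM_TO_SIGMA = 2.3548200450309493


@dataclass(frozen=True)
class ReconConfig:
    n_iterations: int = 8
    n_subsets: int = 5
    psf_fwhm_mm: float = 0.0
    postfilter_fwhm_mm: float = 0.0
    tof: bool = False
    grid: VoxelGrid | None = None
    eps_rel: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("iterations and subsets must be >= 1")
        if self.eps_rel <= 0:
            raise ValueError("eps must be > 0")


def _gauss(vol: np.ndarray, grid: VoxelGrid, fwhm_mm: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return vol
    s = fwhm_mm / _FWHM_TO_SIGMA
    return gaussian_filter(vol, (s / grid.dz, s / grid.dy, s / grid.dx), mode="constant")


def op_osem(
    prompts: Sinogram,
    randoms_or_delayed: Sinogram,
    scatter: Sinogram,
    attn: Sinogram,
    g: ScannerGeometry,
    cfg: ReconConfig,
) -> VolumeImage:
    """OP-OSEM reconstruction; returns a counts-domain image on ``cfg.grid``.

    ``randoms_or_delayed`` and ``scatter`` enter as additive terms of
    the Poisson model; ``attn`` multiplies the projection.  Additive
    estimates without a TOF axis are spread uniformly over TOF bins
    when ``cfg.tof`` is set (randoms are TOF-uniform by construction).
    Voxels with zero subset sensitivity are masked to 0.
    """
    if cfg.grid is None:
        raise ValueError("ReconConfig.grid (output grid) is required")
    if np.any(prompts.values < 0):
        raise ValueError("prompts must be >= 0")
    for s in (randoms_or_delayed, scatter, attn):
        if s.geometry != g:
            raise ValueError("sinogram geometry mismatch")

    grid = cfg.grid
    plan = get_plan(g, grid)
    tof = cfg.tof

    def _match(v: np.ndarray) -> np.ndarray:
        """Align a sinogram with the reconstruction's TOF dimensionality."""
        if tof and v.ndim == 3:
            return np.repeat(v[..., None], g.n_tof_bins, axis=-1) / g.n_tof_bins
        if not tof and v.ndim == 4:
            return v.sum(axis=-1)
        return v

    p = _match(prompts.values)
    add = _match(randoms_or_delayed.values) + _match(scatter.values)
    attn_v = attn.values[..., None] if tof else attn.values

    if g.n_views % cfg.n_subsets != 0:
        warnings.warn(
            f"n_views={g.n_views} not divisible by n_subsets={cfg.n_subsets}; "
            "using unbalanced view-interleaved subsets",
            stacklevel=2,
        )
    if cfg.n_subsets > g.n_views:
        raise ValueError("more subsets than views")
    subsets = [np.arange(u, g.n_views, cfg.n_subsets) for u in range(cfg.n_subsets)]

    def fwd(x: np.ndarray, views: np.ndarray) -> np.ndarray:
        return attn_v[:, views] * plan.forward(
            _gauss(x, grid, cfg.psf_fwhm_mm), views=views, tof=tof
        )

    def bck(y: np.ndarray, views: np.ndarray) -> np.ndarray:
        return _gauss(plan.back(attn_v[:, views] * y, views=views, tof=tof), grid, cfg.psf_fwhm_mm)

    eps = cfg.eps_rel * max(p.mean(), np.finfo(float).tiny)

    sens = [bck(np.ones_like(p[:, views]), views) for views in subsets]
    masks = [s > 0 for s in sens]
    if not all(m.all() for m in masks):
        warnings.warn("voxels with zero subset sensitivity are masked to 0", stacklevel=2)

    x = np.where(plan.support, 1.0, 0.0)
    for _ in range(cfg.n_iterations):
        for views, s_u, m_u in zip(subsets, sens, masks):
            denom = fwd(x, views) + add[:, views]
            ratio = p[:, views] / np.maximum(denom, eps)
            upd = bck(ratio, views)
            np.divide(x * upd, s_u, out=x, where=m_u)
            x[~m_u] = 0.0

    if cfg.postfilter_fwhm_mm > 0:
        x = _gauss(x, grid, cfg.postfilter_fwhm_mm)
    return VolumeImage(np.maximum(x, 0.0), grid, quantity="reconstructed")


def poisson_loglik(prompts: np.ndarray, model: np.ndarray) -> float:
    """Poisson log-likelihood sum(p*log m - m), constants dropped.

    Bins with model = 0 and prompts > 0 contribute -inf (reported, not
    raised); bins with prompts = 0 contribute -m.
    """
    p = np.asarray(prompts, dtype=np.float64)
    m = np.asarray(model, dtype=np.float64)
    if np.any((m == 0) & (p > 0)):
        return float("-inf")
    out = -m.sum()
    pos = p > 0
    out += float((p[pos] * np.log(m[pos])).sum())
    return float(out)
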