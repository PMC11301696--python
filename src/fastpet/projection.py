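"""Joseph-method forward / back projection in sinogram coordinates.

Each sinogram plane is treated as a direct (in-plane) 2D projection at
its own axial position; the axial dimension is handled by a linear
interpolation operator between image-slice positions and sinogram-plane
positions (the obliqueness removed by span compression is absorbed into
the pre-smoothing kernel upstream).  The in-plane projector follows
Joseph's method: rays are stepped along their dominant axis and sampled
by linear interpolation along the other axis, with ties between
dominant axes broken toward x.

Both operators are materialized as one sparse matrix per view, so the
back projector is the *exact* adjoint of the forward projector (matrix
transpose), which is what makes the EM reconstruction testable against
its monotonicity guarantee.

Two conventions coexist:

* **physical line integrals** (``Plan.forward_raw``) -- entries are
  interpolation weight x step length in mm.  Used for attenuation
  factors, where exp(-integral) must be in true units.
* **counts-preserving projection** (``Plan.forward``) -- the raw
  operator composed with a per-voxel normalization ``D = diag(1/c)``
  where ``c = A^T 1``, so that the total sinogram value equals the
  total image value for any non-negative image supported inside the
  scanner bore.  This is the convention under which the cps/kBq
  sensitivity calibration is exact.

With TOF enabled, every ray contribution is spread over the TOF bins by
a Gaussian kernel (sigma from the coincidence timing resolution)
centered on the emission point's position along the LOR, truncated at
+/-3 sigma and renormalized, so summing over TOF bins reproduces the
non-TOF operator exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ScannerGeometry, VoxelGrid, validate_geometry
from .phantom import VolumeImage


@dataclass
class Sinogram:
    """Projection-space data indexed ``(plane, view, projection[, tof_bin])``."""

    values: np.ndarray
    geometry: ScannerGeometry
    tof: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = self.geometry.sinogram_shape(self.tof)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy_with(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(values=values, geometry=self.geometry, tof=self.tof)


def _view_entries(g: ScannerGeometry, grid: VoxelGrid, view: int):
    """Sparse entries of the 2D Joseph operator for one view.

    Returns (row, col, weight_mm, t_mm): sinogram radial bin, flattened
    (y, x) pixel, weight including the path step length, and the
    emission position along the LOR (for TOF spreading).
    """
    n_s = g.n_projections
    ds = g.radial_spacing_mm
    phi = math.pi * view / g.n_views
    cphi, sphi = math.cos(phi), math.sin(phi)
    s = (np.arange(n_s) - (n_s - 1) / 2.0) * ds
    x0, y0, _ = grid.origin

    # ray: p(t) = s*(cos, sin) + t*(-sin, cos)
    if abs(sphi) >= abs(cphi):  # dominant axis x (ties toward x)
        xi = x0 + np.arange(grid.nx) * grid.dx
        t = (s[None, :] * cphi - xi[:, None]) / sphi          # (nx, n_s)
        other = s[None, :] * sphi + t * cphi                  # y positions
        f = (other - y0) / grid.dy
        step = grid.dx / abs(sphi)
        n_interp = grid.ny

        def _col(fixed_idx, interp_idx):
            return interp_idx * grid.nx + fixed_idx

        n_fixed = grid.nx
    else:  # dominant axis y
        yj = y0 + np.arange(grid.ny) * grid.dy
        t = (yj[:, None] - s[None, :] * sphi) / cphi          # (ny, n_s)
        other = s[None, :] * cphi - t * sphi                  # x positions
        f = (other - x0) / grid.dx
        step = grid.dy / abs(cphi)
        n_interp = grid.nx

        def _col(fixed_idx, interp_idx):
            return fixed_idx * grid.nx + interp_idx

        n_fixed = grid.ny

    j0 = np.floor(f).astype(np.int64)
    w1 = f - j0
    w0 = 1.0 - w1
    fixed = np.broadcast_to(np.arange(n_fixed)[:, None], f.shape)
    rows_base = np.broadcast_to(np.arange(n_s)[None, :], f.shape)

    out_r, out_c, out_w, out_t = [], [], [], []
    for jj, ww in ((j0, w0), (j0 + 1, w1)):
        valid = (jj >= 0) & (jj < n_interp) & (ww > 0)
        out_r.append(rows_base[valid])
        out_c.append(_col(fixed[valid], jj[valid]))
        out_w.append(ww[valid] * step)
        out_t.append(np.broadcast_to(t, f.shape)[valid])
    return (
        np.concatenate(out_r),
        np.concatenate(out_c),
        np.concatenate(out_w),
        np.concatenate(out_t),
    )


def axial_interp_matrix(g: ScannerGeometry, slice_z: np.ndarray) -> sp.csr_matrix:
    """Sparse (n_planes x n_slices) linear-interpolation operator.

    Each sinogram plane receives the value interpolated between the two
    nearest slice axial positions, clamped at the ends.
    """
    slice_z = np.asarray(slice_z, dtype=np.float64)
    nz = slice_z.size
    pz = g.plane_z_positions()
    if nz == 1:
        return sp.csr_matrix(np.ones((g.n_planes, 1)))
    dz = slice_z[1] - slice_z[0]
    f = np.clip((pz - slice_z[0]) / dz, 0.0, nz - 1.0)
    k0 = np.minimum(np.floor(f).astype(np.int64), nz - 2)
    w1 = f - k0
    rows = np.repeat(np.arange(g.n_planes), 2)
    cols = np.stack([k0, k0 + 1], axis=1).ravel()
    data = np.stack([1.0 - w1, w1], axis=1).ravel()
    return sp.csr_matrix((data, (rows, cols)), shape=(g.n_planes, nz))


class Plan:
    """Cached projection operators for one (geometry, grid) pair."""

    def __init__(self, g: ScannerGeometry, grid: VoxelGrid):
        problems = validate_geometry(g, grid)
        if problems:
            raise ValueError("invalid geometry/grid: " + "; ".join(problems))
        self.geometry = g
        self.grid = grid
        self.npix = grid.nx * grid.ny
        self._entries = [_view_entries(g, grid, v) for v in range(g.n_views)]
        self.P = [
            sp.csr_matrix((w, (r, c)), shape=(g.n_projections, self.npix))
            for (r, c, w, _) in self._entries
        ]
        _, _, z = grid.axis_centers()
        self.L = axial_interp_matrix(g, z)
        self.plane_weight = np.asarray(self.L.sum(axis=0)).ravel()      # (nz,)
        q = np.zeros(self.npix)
        for P in self.P:
            q += np.asarray(P.sum(axis=0)).ravel()
        self.pixel_weight = q
        c = self.plane_weight[:, None] * q[None, :]
        self.c = c.reshape(grid.shape)
        self.support = self.c > 0
        self._tof_P: list[list[sp.csr_matrix]] | None = None

    # -- TOF ----------------------------------------------------------------
    def _tof_matrices(self) -> list[list[sp.csr_matrix]]:
        if self._tof_P is None:
            g = self.geometry
            centers = g.tof_bin_centers_mm()
            sigma = g.tof_sigma_mm
            mats: list[list[sp.csr_matrix]] = []
            for (r, c, w, t) in self._entries:
                d = t[:, None] - centers[None, :]
                wb = np.exp(-0.5 * (d / sigma) ** 2)
                wb[np.abs(d) > 3 * sigma] = 0.0
                norm = wb.sum(axis=1)
                dead = norm <= 0
                if np.any(dead):  # beyond the last bin's +/-3 sigma: nearest bin
                    nearest = np.abs(d[dead]).argmin(axis=1)
                    wb[dead] = 0.0
                    wb[np.nonzero(dead)[0], nearest] = 1.0
                    norm = wb.sum(axis=1)
                wb /= norm[:, None]
                mats.append(
                    [
                        sp.csr_matrix(
                            (w * wb[:, b], (r, c)),
                            shape=(g.n_projections, self.npix),
                        )
                        for b in range(g.n_tof_bins)
                    ]
                )
            self._tof_P = mats
        return self._tof_P

    # -- raw (physical line-integral) operators -----------------------------
    def forward_raw(
        self, vol: np.ndarray, views: np.ndarray | None = None, tof: bool = False
    ) -> np.ndarray:
        g = self.geometry
        views = np.arange(g.n_views) if views is None else np.asarray(views)
        nz = self.grid.nz
        X = np.ascontiguousarray(vol.reshape(nz, self.npix).T)  # (npix, nz)
        nv = len(views)
        if not tof:
            S = np.empty((nz, nv, g.n_projections))
            for k, v in enumerate(views):
                S[:, k, :] = (self.P[v] @ X).T
            out = self.L @ S.reshape(nz, -1)
            return out.reshape(g.n_planes, nv, g.n_projections)
        mats = self._tof_matrices()
        S = np.empty((nz, nv, g.n_projections, g.n_tof_bins))
        for k, v in enumerate(views):
            for b in range(g.n_tof_bins):
                S[:, k, :, b] = (mats[v][b] @ X).T
        out = self.L @ S.reshape(nz, -1)
        return out.reshape(g.n_planes, nv, g.n_projections, g.n_tof_bins)

    def back_raw(
        self, sino: np.ndarray, views: np.ndarray | None = None, tof: bool = False
    ) -> np.ndarray:
        g = self.geometry
        views = np.arange(g.n_views) if views is None else np.asarray(views)
        nz = self.grid.nz
        nv = len(views)
        S = (self.L.T @ sino.reshape(g.n_planes, -1)).reshape(
            (nz, nv, g.n_projections) + ((g.n_tof_bins,) if tof else ())
        )
        X = np.zeros((self.npix, nz))
        if not tof:
            for k, v in enumerate(views):
                X += self.P[v].T @ np.ascontiguousarray(S[:, k, :].T)
        else:
            mats = self._tof_matrices()
            for k, v in enumerate(views):
                for b in range(g.n_tof_bins):
                    X += mats[v][b].T @ np.ascontiguousarray(S[:, k, :, b].T)
        return X.T.reshape(self.grid.shape)

    # -- counts-preserving operators ----------------------------------------
    def normalize_volume(self, vol: np.ndarray) -> np.ndarray:
        out = np.zeros_like(vol, dtype=np.float64)
        np.divide(vol, self.c, out=out, where=self.support)
        return out

    def forward(
        self, vol: np.ndarray, views: np.ndarray | None = None, tof: bool = False
    ) -> np.ndarray:
        return self.forward_raw(self.normalize_volume(vol), views=views, tof=tof)

    def back(
        self, sino: np.ndarray, views: np.ndarray | None = None, tof: bool = False
    ) -> np.ndarray:
        return self.normalize_volume(self.back_raw(sino, views=views, tof=tof))


_PLAN_CACHE: dict[tuple[ScannerGeometry, VoxelGrid], Plan] = {}


def get_plan(g: ScannerGeometry, grid: VoxelGrid) -> Plan:
    key = (g, grid)
    if key not in _PLAN_CACHE:
        if len(_PLAN_CACHE) > 8:  # plans can be large; keep the cache small
            _PLAN_CACHE.clear()
        _PLAN_CACHE[key] = Plan(g, grid)
    return _PLAN_CACHE[key]


# --- public operations ------------------------------------------------------

def forward_project(img: VolumeImage, g: ScannerGeometry, tof: bool = False) -> Sinogram:
    """Counts-preserving Joseph forward projection of a volume.

    For any non-negative image supported inside the bore, the total
    sinogram value equals the total image value (TOF bins included).
    """
    if np.any(img.values < 0):
        raise ValueError("forward_project requires a non-negative image")
    plan = get_plan(g, img.grid)
    return Sinogram(plan.forward(img.values, tof=tof), g, tof=tof)


def back_project(s: Sinogram, g: ScannerGeometry, grid: VoxelGrid) -> VolumeImage:
    """Exact adjoint of :func:`forward_project` on the same geometry/grid."""
    if s.geometry != g:
        raise ValueError("sinogram geometry does not match the requested geometry")
    plan = get_plan(g, grid)
    return VolumeImage(plan.back(s.values, tof=s.tof), grid, quantity="reconstructed")


def attenuation_factors(mu: VolumeImage, g: ScannerGeometry) -> Sinogram:
    """Per-LOR survival factors exp(-integral mu dl), in (0, 1].

    ``mu`` is in cm^-1; path lengths are computed in mm and converted.
    No counts normalization is applied to this physical line integral.
    """
    if np.any(mu.values < 0):
        raise ValueError("attenuation coefficients must be >= 0")
    plan = get_plan(g, mu.grid)
    integ_mm = plan.forward_raw(mu.values)
    return Sinogram(np.exp(-0.1 * integ_mm), g, tof=False)
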