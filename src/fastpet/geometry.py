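"""Scanner and image-grid geometry.

The simulator describes a cylindrical PET scanner directly in sinogram
coordinates: a line of response (LOR) is addressed by its radial offset
(projection bin), azimuthal view and axial plane, optionally by a
time-of-flight (TOF) bin.  Crystal-level detail (ring count, crystal
pitch, gaps) is deliberately not modelled: every pipeline stage operates
on sinograms, so the sinogram dimensioning *is* the geometry.

The ``vision600`` preset mirrors the Siemens Biograph Vision-600 data
format: 520 projections x 50 views (after angular mashing) x 815 axial
planes (after span-19 compression) x 33 TOF bins, with a 72.6 x 72.6 x
26.2 cm^3 field of view sampled on a 440 x 440 x 159 voxel grid.  The
815 axial planes are laid out uniformly over the axial FOV; the oblique
segment structure collapsed by span compression is not modelled
individually (the michelogram cannot be reconstructed from the plane
count alone), so every plane behaves as a direct plane at its own axial
position.
"""

from __future__ import annotations

import configparser
import io as _io
import math
from dataclasses import dataclass, replace, fields

import numpy as np

#: speed of light, mm per picosecond (used to convert TOF timing to distance)
SPEED_OF_LIGHT_MM_PER_PS = 0.299792458


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel lattice.

    ``origin`` is the physical coordinate (mm) of the *center* of voxel
    (0, 0, 0); if omitted it is chosen so the grid is centered on the
    scanner axis.  Arrays defined on a grid use C order ``(z, y, x)``
    with x fastest.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel edge lengths must be > 0")
        if self.origin is None:
            object.__setattr__(
                self,
                "origin",
                (
                    -(self.nx - 1) / 2.0 * self.dx,
                    -(self.ny - 1) / 2.0 * self.dy,
                    -(self.nz - 1) / 2.0 * self.dz,
                ),
            )
        else:
            object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        return (self.nz, self.ny, self.nx)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent (mm) per axis: count x edge length."""
        return (self.nx * self.dx, self.ny * self.dy, self.nz * self.dz)

    @property
    def voxel_volume_ml(self) -> float:
        return self.dx * self.dy * self.dz / 1000.0

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates ``(x, y, z)`` in mm."""
        x0, y0, z0 = self.origin
        return (
            x0 + np.arange(self.nx) * self.dx,
            y0 + np.arange(self.ny) * self.dy,
            z0 + np.arange(self.nz) * self.dz,
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable center-coordinate arrays (X, Y, Z) shaped for (z, y, x)."""
        x, y, z = self.axis_centers()
        return x[None, None, :], y[None, :, None], z[:, None, None]


@dataclass(frozen=True)
class ScannerGeometry:
    """Physical scanner description plus sinogram dimensioning."""

    name: str
    ring_radius_mm: float
    n_projections: int
    n_views: int
    n_planes: int
    span: int
    n_tof_bins: int
    tof_bin_width_ps: float
    timing_resolution_ps: float
    fov_transaxial_mm: float
    fov_axial_mm: float

    @property
    def radial_spacing_mm(self) -> float:
        return self.fov_transaxial_mm / self.n_projections

    @property
    def tof_bin_width_mm(self) -> float:
        # a time difference dt localizes the emission at c*dt/2 along the LOR
        return 0.5 * SPEED_OF_LIGHT_MM_PER_PS * self.tof_bin_width_ps

    @property
    def tof_sigma_mm(self) -> float:
        fwhm_mm = 0.5 * SPEED_OF_LIGHT_MM_PER_PS * self.timing_resolution_ps
        return fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def sinogram_shape(self, tof: bool = False) -> tuple[int, ...]:
        shape: tuple[int, ...] = (self.n_planes, self.n_views, self.n_projections)
        if tof:
            shape = shape + (self.n_tof_bins,)
        return shape

    def radial_offsets_mm(self) -> np.ndarray:
        n = self.n_projections
        return (np.arange(n) - (n - 1) / 2.0) * self.radial_spacing_mm

    def view_angles(self) -> np.ndarray:
        return np.pi * np.arange(self.n_views) / self.n_views

    def plane_z_positions(self) -> np.ndarray:
        """Axial position (mm) of each sinogram plane, uniform over the axial FOV."""
        n = self.n_planes
        return (np.arange(n) - (n - 1) / 2.0) * (self.fov_axial_mm / n)

    def tof_bin_centers_mm(self) -> np.ndarray:
        n = self.n_tof_bins
        return (np.arange(n) - (n - 1) / 2.0) * self.tof_bin_width_mm


def make_vision600() -> tuple[ScannerGeometry, VoxelGrid]:
    """Vision-600 preset: sinogram format 520 x 50 x 815 x 33 (span 19) on a
    440 x 440 x 159 grid of 1.65 x 1.65 x 1.646 mm voxels.

    TOF bin width and coincidence timing resolution are not part of the
    published dimensioning; the defaults (169 ps bins, 210 ps FWHM timing)
    are typical Vision settings and are plain dataclass fields, so callers
    may override them with :func:`dataclasses.replace`.
    """
    geom = ScannerGeometry(
        name="vision600",
        ring_radius_mm=410.0,
        n_projections=520,
        n_views=50,
        n_planes=815,
        span=19,
        n_tof_bins=33,
        tof_bin_width_ps=169.0,
        timing_resolution_ps=210.0,
        fov_transaxial_mm=726.0,
        fov_axial_mm=261.714,
    )
    grid = VoxelGrid(nx=440, ny=440, nz=159, dx=1.65, dy=1.65, dz=1.646)
    return geom, grid


def make_scaled_geometry(scale: float) -> tuple[ScannerGeometry, VoxelGrid]:
    """Deterministic desk-scale variant of the Vision-600 preset.

    All sinogram and grid *counts* are scaled (round half up, minimum 1,
    TOF bin count forced odd) while the physical FOV is preserved, so the
    voxel / radial spacings grow as the counts shrink.  ``scale=1`` returns
    the preset unchanged.
    """
    if not (0 < scale <= 1):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    geom, grid = make_vision600()
    if scale == 1:
        return geom, grid

    def sc(count: int) -> int:
        return max(1, _round_half_up(count * scale))

    n_tof = sc(geom.n_tof_bins)
    if n_tof % 2 == 0:
        n_tof += 1
    geom = replace(
        geom,
        name=f"vision600:{scale:g}",
        n_projections=sc(geom.n_projections),
        n_views=sc(geom.n_views),
        n_planes=sc(geom.n_planes),
        n_tof_bins=n_tof,
    )
    nx, ny, nz = sc(grid.nx), sc(grid.ny), sc(grid.nz)
    ex, ey, ez = grid.extent_mm
    grid = VoxelGrid(nx=nx, ny=ny, nz=nz, dx=ex / nx, dy=ey / ny, dz=ez / nz)
    return geom, grid


def validate_geometry(g: ScannerGeometry, grid: VoxelGrid) -> list[str]:
    """Collect invariant violations (empty list means valid).

    Violations are returned as messages rather than raised so that a
    configuration loader can report all problems at once.
    """
    problems: list[str] = []
    for attr in ("n_projections", "n_views", "n_planes", "n_tof_bins"):
        if getattr(g, attr) < 1:
            problems.append(f"{attr} must be >= 1 (got {getattr(g, attr)})")
    if g.n_tof_bins % 2 == 0:
        problems.append(
            f"n_tof_bins must be odd (symmetric around zero time difference), got {g.n_tof_bins}"
        )
    if g.fov_transaxial_mm >= 2 * g.ring_radius_mm:
        problems.append(
            "transaxial FOV must fit inside the detector ring: "
            f"fov {g.fov_transaxial_mm} mm >= bore {2 * g.ring_radius_mm} mm"
        )
    ex, ey, _ = grid.extent_mm
    if max(ex, ey) > g.fov_transaxial_mm * (1 + 1e-9):
        problems.append(
            f"grid transaxial extent {max(ex, ey):.3f} mm exceeds the bore / transaxial FOV "
            f"{g.fov_transaxial_mm:.3f} mm"
        )
    if min(grid.dx, grid.dy, grid.dz) <= 0 or min(grid.nx, grid.ny, grid.nz) < 1:
        problems.append("grid has non-positive counts or spacings")
    return problems


# --- config-file (de)serialization -----------------------------------------

_GEOMETRY_SECTION = "geometry"
_GRID_SECTION = "grid"


def geometry_to_text(g: ScannerGeometry, grid: VoxelGrid) -> str:
    """Serialize a preset to flat key-value text (INI dialect)."""
    cp = configparser.ConfigParser()
    cp[_GEOMETRY_SECTION] = {f.name: str(getattr(g, f.name)) for f in fields(g)}
    cp[_GRID_SECTION] = {
        "nx": str(grid.nx),
        "ny": str(grid.ny),
        "nz": str(grid.nz),
        "dx": repr(grid.dx),
        "dy": repr(grid.dy),
        "dz": repr(grid.dz),
        "origin": ",".join(repr(v) for v in grid.origin),
    }
    buf = _io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def geometry_from_text(text: str) -> tuple[ScannerGeometry, VoxelGrid]:
    cp = configparser.ConfigParser()
    cp.read_string(text)
    gsec = cp[_GEOMETRY_SECTION]
    name = gsec.get("name", "custom")
    if name == "vision600" and len(gsec) <= 1:
        return make_vision600()
    ints = {"n_projections", "n_views", "n_planes", "span", "n_tof_bins"}
    kwargs = {}
    for f in fields(ScannerGeometry):
        if f.name == "name":
            kwargs[f.name] = gsec[f.name]
        elif f.name in ints:
            kwargs[f.name] = int(gsec[f.name])
        else:
            kwargs[f.name] = float(gsec[f.name])
    geom = ScannerGeometry(**kwargs)
    s = cp[_GRID_SECTION]
    grid = VoxelGrid(
        nx=int(s["nx"]),
        ny=int(s["ny"]),
        nz=int(s["nz"]),
        dx=float(s["dx"]),
        dy=float(s["dy"]),
        dz=float(s["dz"]),
        origin=tuple(float(v) for v in s["origin"].split(",")),
    )
    return geom, grid


def resolve_preset(spec: str) -> tuple[ScannerGeometry, VoxelGrid]:
    """Resolve ``"vision600"`` or ``"vision600:<scale>"`` to a geometry pair."""
    if spec == "vision600":
        return make_vision600()
    if spec.startswith("vision600:"):
        return make_scaled_geometry(float(spec.split(":", 1)[1]))
    raise ValueError(f"unknown geometry preset {spec!r}")
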