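"""Voxelized activity / attenuation phantoms.

Two generators are provided:

* :func:`make_nema_iq` -- the NEMA image-quality phantom: six fillable
  spheres (inner diameters 10-37 mm) in a warm background shell of
  about 9575 ml, used to calibrate and validate the simulator.
* :func:`make_synthetic_torso` -- a parametric torso (body, lungs,
  liver, spleen, spine, spherical lesions) that stands in for clinical
  FDG images in the feature / segmentation experiments.

Phantoms are described by an ordered list of geometric primitives
(later shapes override earlier ones) and rasterized with sub-voxel
supersampling so that edge voxels carry volume-weighted mixtures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import VoxelGrid

Quantity = Literal["activity", "attenuation", "reconstructed", "labels"]

#: linear attenuation of water at 511 keV, cm^-1
MU_WATER_CM = 0.096

#: printed NEMA IQ filling: background / sphere activity concentration, Bq/ml
NEMA_BG_BQ_ML = 2930.0
NEMA_SPHERE_BQ_ML = 27369.0
#: interior background volume of the NEMA body shell, ml
NEMA_BODY_VOLUME_ML = 9575.0
#: inner diameters of the six fillable spheres, mm (sphere 1..6)
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
#: distance of the sphere centers from the phantom axis, mm (NEMA NU-2)
NEMA_SPHERE_RING_RADIUS_MM = 57.2
#: interior axial length of the body cavity, mm (NEMA NU-2)
NEMA_BODY_LENGTH_MM = 180.0
#: flat-chamfer depth of the D-shaped body, as a fraction of its radius
_NEMA_CHAMFER = 0.7


@dataclass
class VolumeImage:
    """A 3D scalar field on a :class:`VoxelGrid`.

    ``values`` has shape ``grid.shape == (nz, ny, nx)``.
    """

    values: np.ndarray
    grid: VoxelGrid
    quantity: Quantity = "activity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.quantity in ("activity", "attenuation") and np.any(self.values < 0):
            raise ValueError(f"{self.quantity} values must be >= 0")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy_with(self, values: np.ndarray) -> "VolumeImage":
        return VolumeImage(values=values, grid=self.grid, quantity=self.quantity)


@dataclass(frozen=True)
class Shape:
    """One phantom primitive.

    size parameters (mm):
      sphere             -- (radius,)
      cylinder           -- (radius, half_length); axis along z
      elliptic_cylinder  -- (semi_x, semi_y, half_length); axis along z
      chamfered_cylinder -- (radius, half_length, chamfer_frac); circular
                            cylinder with the region y < -chamfer_frac*radius
                            cut off (a "D" cross-section)
      ellipsoid          -- (semi_x, semi_y, semi_z)
      box                -- (len_x, len_y, len_z) full edge lengths
    """

    primitive: str
    center: tuple[float, float, float]
    size: tuple[float, ...]
    activity: float
    attenuation: float
    label: int = 0

    def __post_init__(self) -> None:
        if self.activity < 0 or self.attenuation < 0:
            raise ValueError("activity and attenuation must be >= 0")
        if any(s <= 0 for s in self.size[: 2 if self.primitive == "chamfered_cylinder" else None]):
            raise ValueError("size parameters must be > 0")

    def inside(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        u, v, w = x - cx, y - cy, z - cz
        p = self.primitive
        if p == "sphere":
            (r,) = self.size
            return u * u + v * v + w * w <= r * r
        if p == "cylinder":
            r, hl = self.size
            return (u * u + v * v <= r * r) & (np.abs(w) <= hl)
        if p == "elliptic_cylinder":
            a, b, hl = self.size
            return ((u / a) ** 2 + (v / b) ** 2 <= 1.0) & (np.abs(w) <= hl)
        if p == "chamfered_cylinder":
            r, hl, ch = self.size
            return (u * u + v * v <= r * r) & (np.abs(w) <= hl) & (v >= -ch * r)
        if p == "ellipsoid":
            a, b, c = self.size
            return (u / a) ** 2 + (v / b) ** 2 + (w / c) ** 2 <= 1.0
        if p == "box":
            lx, ly, lz = self.size
            return (np.abs(u) <= lx / 2) & (np.abs(v) <= ly / 2) & (np.abs(w) <= lz / 2)
        raise ValueError(f"unknown primitive {p!r}")

    def bounding_box(self) -> tuple[tuple[float, float], ...]:
        cx, cy, cz = self.center
        p = self.primitive
        if p == "sphere":
            (r,) = self.size
            half = (r, r, r)
        elif p == "cylinder":
            r, hl = self.size
            half = (r, r, hl)
        elif p == "elliptic_cylinder":
            a, b, hl = self.size
            half = (a, b, hl)
        elif p == "chamfered_cylinder":
            r, hl, _ = self.size
            half = (r, r, hl)
        elif p == "ellipsoid":
            half = self.size
        elif p == "box":
            half = tuple(s / 2 for s in self.size)
        else:
            raise ValueError(p)
        return tuple((c - h, c + h) for c, h in zip((cx, cy, cz), half))


@dataclass
class PhantomSpec:
    """Ordered shape list; later shapes override earlier ones."""

    shapes: list[Shape] = field(default_factory=list)

    def add(self, shape: Shape) -> None:
        self.shapes.append(shape)

    def spheres(self) -> list[Shape]:
        return [s for s in self.shapes if s.primitive == "sphere"]


def _shape_fraction(shape: Shape, grid: VoxelGrid, supersample: int) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Coverage fraction of ``shape`` per voxel inside its bounding box."""
    xs, ys, zs = grid.axis_centers()
    (bx, by, bz) = shape.bounding_box()

    def _rng(centers: np.ndarray, d: float, lo: float, hi: float) -> slice:
        i0 = int(np.searchsorted(centers, lo - d))
        i1 = int(np.searchsorted(centers, hi + d))
        return slice(max(0, i0), min(len(centers), i1 + 1))

    sx = _rng(xs, grid.dx, *bx)
    sy = _rng(ys, grid.dy, *by)
    sz = _rng(zs, grid.dz, *bz)
    if sx.start >= sx.stop or sy.start >= sy.stop or sz.start >= sz.stop:
        return np.zeros((0, 0, 0)), (slice(0, 0),) * 3

    X = xs[sx][None, None, :]
    Y = ys[sy][None, :, None]
    Z = zs[sz][:, None, None]
    ss = supersample
    if ss == 1:
        frac = shape.inside(X, Y, Z).astype(np.float32)
    else:
        offs = (np.arange(ss) + 0.5) / ss - 0.5
        frac = np.zeros((sz.stop - sz.start, sy.stop - sy.start, sx.stop - sx.start), np.float32)
        for oz in offs:
            for oy in offs:
                for ox in offs:
                    frac += shape.inside(
                        X + ox * grid.dx, Y + oy * grid.dy, Z + oz * grid.dz
                    )
        frac /= ss**3
    return frac, (sz, sy, sx)


def rasterize(
    spec: PhantomSpec,
    grid: VoxelGrid,
    quantity: Quantity = "activity",
    supersample: int = 3,
) -> VolumeImage:
    """Rasterize one field of a phantom spec.

    Each voxel receives the volume-weighted mixture of shape values on a
    ``supersample**3`` sub-grid; ``supersample=1`` degenerates to
    center-point assignment.  Later shapes composite over earlier ones
    with their coverage fraction (last-wins on full coverage).
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    vol = np.zeros(grid.shape, np.float64)
    for shape in spec.shapes:
        value = shape.activity if quantity == "activity" else shape.attenuation
        frac, sl = _shape_fraction(shape, grid, supersample)
        if frac.size == 0:
            continue
        region = vol[sl]
        vol[sl] = region * (1.0 - frac) + value * frac
    return VolumeImage(values=vol, grid=grid, quantity=quantity)


def rasterize_pair(
    spec: PhantomSpec, grid: VoxelGrid, supersample: int = 3
) -> tuple[VolumeImage, VolumeImage]:
    """Rasterize activity and attenuation sharing one coverage computation."""
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    act = np.zeros(grid.shape, np.float64)
    att = np.zeros(grid.shape, np.float64)
    for shape in spec.shapes:
        frac, sl = _shape_fraction(shape, grid, supersample)
        if frac.size == 0:
            continue
        act[sl] = act[sl] * (1.0 - frac) + shape.activity * frac
        att[sl] = att[sl] * (1.0 - frac) + shape.attenuation * frac
    return (
        VolumeImage(act, grid, "activity"),
        VolumeImage(att, grid, "attenuation"),
    )


def nema_body_radius_mm(volume_ml: float = NEMA_BODY_VOLUME_ML) -> float:
    """Radius of the chamfered-cylinder body whose cavity volume matches the shell.

    Cross-section area of a circle of radius R with the region
    y < -c*R removed: R^2 * (pi - acos(c) + c*sqrt(1-c^2)).
    """
    c = _NEMA_CHAMFER
    area_coeff = math.pi - (math.acos(c) - c * math.sqrt(1 - c * c))
    return math.sqrt(volume_ml * 1000.0 / (NEMA_BODY_LENGTH_MM * area_coeff))


def nema_sphere_centers_mm(plane_z_mm: float = 0.0) -> list[tuple[float, float, float]]:
    """Six sphere centers, 57.2 mm from the axis on a common transaxial plane."""
    centers = []
    for k in range(6):
        ang = math.radians(60.0 * k + 30.0)
        centers.append(
            (
                NEMA_SPHERE_RING_RADIUS_MM * math.cos(ang),
                NEMA_SPHERE_RING_RADIUS_MM * math.sin(ang),
                plane_z_mm,
            )
        )
    return centers


def make_nema_iq(
    grid: VoxelGrid,
    bg_conc: float = NEMA_BG_BQ_ML,
    sphere_conc: float = NEMA_SPHERE_BQ_ML,
    mu_water: float = MU_WATER_CM,
    supersample: int = 3,
) -> tuple[VolumeImage, VolumeImage, PhantomSpec]:
    """NEMA IQ phantom: warm D-shaped body (~9575 ml) with six hot spheres.

    The sphere wall thickness is ignored (inner diameters used directly)
    and the lung insert is omitted: attenuation is water inside the body
    shell and zero elsewhere, matching the simplified map used for
    calibration.  Default concentrations give the printed 9.34:1
    sphere-to-background ratio.
    """
    spec = PhantomSpec()
    R = nema_body_radius_mm()
    spec.add(
        Shape(
            "chamfered_cylinder",
            (0.0, 0.0, 0.0),
            (R, NEMA_BODY_LENGTH_MM / 2.0, _NEMA_CHAMFER),
            activity=bg_conc,
            attenuation=mu_water,
            label=1,
        )
    )
    for i, (d, c) in enumerate(zip(NEMA_SPHERE_DIAMETERS_MM, nema_sphere_centers_mm())):
        spec.add(
            Shape("sphere", c, (d / 2.0,), activity=sphere_conc, attenuation=mu_water, label=2 + i)
        )
    smallest = min(NEMA_SPHERE_DIAMETERS_MM)
    if smallest < 2 * max(grid.dx, grid.dy, grid.dz):
        warnings.warn(
            f"grid too coarse to resolve the {smallest:g} mm sphere "
            f"(< 2 voxels across at {max(grid.dx, grid.dy, grid.dz):g} mm voxels)",
            stacklevel=2,
        )
    act, att = rasterize_pair(spec, grid, supersample=supersample)
    return act, att, spec


#: label values used by :func:`make_synthetic_torso`
TORSO_LABELS = {
    "outside": 0,
    "body": 1,
    "lung_left": 2,
    "lung_right": 3,
    "liver": 4,
    "spleen": 5,
    "spine": 6,
    # lesions take 10, 11, 12, ...
}
TORSO_LESION_LABEL_BASE = 10

#: default lesions: (center mm, diameter mm, uptake ratio over local background)
DEFAULT_TORSO_LESIONS: tuple[tuple[tuple[float, float, float], float, float], ...] = (
    ((-70.0, 20.0, 40.0), 33.0, 5.0),   # right lung
    ((-60.0, -35.0, -45.0), 23.0, 3.0),  # liver dome
    ((20.0, -20.0, 10.0), 16.5, 8.0),   # mediastinal soft tissue
)


def make_synthetic_torso(
    grid: VoxelGrid,
    seed: int,
    lesions: Sequence[tuple[tuple[float, float, float], float, float]] | None = None,
    texture_sigma: float = 0.12,
    supersample: int = 3,
) -> tuple[VolumeImage, VolumeImage, np.ndarray]:
    """Synthetic FDG torso: body, lungs, liver, spleen, spine plus lesions.

    Organ activities (Bq/ml) are plausible 5-min-frame FDG concentrations,
    not a claim about any patient cohort; attenuation is water-like soft
    tissue (0.096 cm^-1), inflated lung (0.03) and bone (0.15).  A mild
    seeded log-normal texture (sigma ``texture_sigma`` of log-intensity,
    smoothed over ~1.5 voxels) multiplies the activity inside the body so
    organs are not perfectly flat.  Lesions are spheres whose activity is
    ``uptake_ratio`` times the local background at their center; a ratio
    of 1 leaves the activity map unchanged there.

    Returns ``(activity, attenuation, label_map)`` where ``label_map``
    follows :data:`TORSO_LABELS` with lesion *i* at ``10 + i``.
    """
    if lesions is None:
        lesions = DEFAULT_TORSO_LESIONS
    hl = min(110.0, 0.45 * grid.nz * grid.dz)
    organs = [
        Shape("elliptic_cylinder", (0, 0, 0), (160.0, 110.0, hl), 3000.0, MU_WATER_CM, label=1),
        Shape("ellipsoid", (85.0, 15.0, 25.0), (48.0, 62.0, 78.0), 500.0, 0.03, label=2),
        Shape("ellipsoid", (-85.0, 15.0, 25.0), (48.0, 62.0, 78.0), 500.0, 0.03, label=3),
        Shape("ellipsoid", (-62.0, -25.0, -52.0), (68.0, 55.0, 48.0), 7000.0, MU_WATER_CM, label=4),
        Shape("ellipsoid", (95.0, -20.0, -55.0), (28.0, 24.0, 34.0), 5500.0, MU_WATER_CM, label=5),
        Shape("cylinder", (0.0, 78.0, 0.0), (16.0, hl), 1500.0, 0.15, label=6),
    ]
    spec = PhantomSpec(list(organs))

    def _background_at(point: tuple[float, float, float]) -> float:
        for shape in reversed(organs):
            x, y, z = (np.array([v]) for v in point)
            if bool(shape.inside(x, y, z)[0]):
                return shape.activity
        return 0.0

    min_edge = min(grid.dx, grid.dy, grid.dz)
    placed: list[Shape] = []
    for i, (center, diameter, ratio) in enumerate(lesions):
        if diameter < 2 * min_edge:
            raise ValueError(
                f"lesion diameter {diameter} mm is below 2 voxels ({2 * min_edge:g} mm)"
            )
        r = diameter / 2.0
        for prev in placed:
            (pr,) = prev.size
            dist = math.dist(center, prev.center)
            if dist < r + pr:
                warnings.warn(
                    f"lesion {i} overlaps an earlier lesion; later shape wins", stacklevel=2
                )
        lesion = Shape(
            "sphere",
            tuple(center),
            (r,),
            activity=ratio * _background_at(tuple(center)),
            attenuation=MU_WATER_CM,
            label=TORSO_LESION_LABEL_BASE + i,
        )
        placed.append(lesion)
        spec.add(lesion)

    act, att = rasterize_pair(spec, grid, supersample=supersample)

    # label map: center-point assignment, last shape wins
    labels = np.zeros(grid.shape, np.int32)
    X, Y, Z = grid.coordinate_grids()
    for shape in spec.shapes:
        labels[shape.inside(X, Y, Z)] = shape.label

    # seeded multiplicative log-normal texture inside the body
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    logfield = rng.normal(0.0, 1.0, grid.shape)
    logfield = gaussian_filter(logfield, sigma=1.5, mode="nearest")
    std = logfield.std()
    if std > 0:
        logfield *= texture_sigma / std
    texture = np.exp(logfield - 0.5 * texture_sigma**2)
    inside_body = labels > 0
    values = act.values.copy()
    values[inside_body] *= texture[inside_body]
    act = VolumeImage(values, grid, "activity")
    return act, att, labels
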