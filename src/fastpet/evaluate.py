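"""Image-quality and feature analysis.

NEMA-IQ side: recovery coefficients (observed/true mean in exact sphere
ROIs), coefficient of variation in a background annulus replicated on 5
adjacent slices, voxel-wise mean/STD maps across noise realizations and
Freedman-Diaconis histograms.

Clinical-feature side: intensity features (peak in a 1 cm^3 sphere
around the hottest voxel, mean, median, skewness, COV) and five GLCM
texture features (joint average, joint entropy, energy, homogeneity,
correlation) built from per-slice symmetric distance-1 co-occurrence
matrices in the four planar directions, pooled over slices per
direction before normalization and averaged over directions.  Paired
feature lists are compared by ordinary least squares with t-based 95%
confidence intervals plus Pearson correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.feature import graycomatrix

from .geometry import VoxelGrid
from .phantom import PhantomSpec, VolumeImage

#: radius (mm) of a 1 cm^3 sphere, used by the "peak" intensity feature
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

_GLCM_ANGLES = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)


@dataclass
class RoiSet:
    """Named binary masks on a shared grid."""

    grid: VoxelGrid
    spheres: dict[float, np.ndarray] = field(default_factory=dict)  # diameter -> mask
    background: np.ndarray | None = None
    other: dict[str, np.ndarray] = field(default_factory=dict)

    def sphere_masks(self) -> list[np.ndarray]:
        return [self.spheres[d] for d in sorted(self.spheres)]

    def sphere_diameters(self) -> list[float]:
        return sorted(self.spheres)


@dataclass
class FeatureVector:
    """Per-ROI intensity + texture features."""

    peak: float
    mean: float
    median: float
    skewness: float
    cov: float
    joint_average: float = float("nan")
    joint_entropy: float = float("nan")
    energy: float = float("nan")
    homogeneity: float = float("nan")
    correlation: float = float("nan")

    INTENSITY_NAMES = ("peak", "mean", "median", "skewness", "cov")
    TEXTURE_NAMES = (
        "joint_average",
        "joint_entropy",
        "energy",
        "homogeneity",
        "correlation",
    )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.INTENSITY_NAMES + self.TEXTURE_NAMES}


def _values(img: VolumeImage | np.ndarray) -> np.ndarray:
    return img.values if isinstance(img, VolumeImage) else np.asarray(img)


def recovery_coefficient(img: VolumeImage, roi: np.ndarray, true_value: float) -> float:
    """RC = mean observed activity in the ROI / true activity."""
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if true_value <= 0:
        raise ValueError("true value must be > 0")
    return float(_values(img)[roi].mean() / true_value)


def cov(img: VolumeImage, roi: np.ndarray) -> float:
    """Coefficient of variation (population SD / mean) within the ROI."""
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    v = _values(img)[roi]
    m = v.mean()
    if m == 0:
        raise ValueError("ROI mean is zero; COV undefined")
    return float(v.std() / m)


def voxelwise_mean_std(realizations: list[VolumeImage]) -> tuple[VolumeImage, VolumeImage]:
    """Element-wise mean and population STD maps across noise realizations."""
    if len(realizations) < 2:
        raise ValueError("need at least 2 realizations")
    grid = realizations[0].grid
    stack = np.stack([_values(r) for r in realizations])
    if any(r.grid != grid for r in realizations):
        raise ValueError("realizations must share a grid")
    return (
        VolumeImage(stack.mean(axis=0), grid, "reconstructed"),
        VolumeImage(stack.std(axis=0), grid, "reconstructed"),
    )


def fd_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with the Freedman-Diaconis bin width 2*IQR*n^(-1/3).

    Degenerate IQR (constant-ish data) falls back to a single bin.
    Returns ``(bin_edges, counts)``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = v.min(), v.max()
    if iqr == 0 or lo == hi:
        edges = np.array([lo, hi if hi > lo else lo + 1.0])
        return edges, np.array([v.size])
    width = 2.0 * iqr * v.size ** (-1.0 / 3.0)
    n_bins = max(1, int(math.ceil((hi - lo) / width)))
    edges = lo + width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # include the maximum
    counts, edges = np.histogram(v, bins=edges)
    return edges, counts


def _skewness(v: np.ndarray) -> float:
    m = v.mean()
    m2 = ((v - m) ** 2).mean()
    if m2 == 0:
        return 0.0
    m3 = ((v - m) ** 3).mean()
    return float(m3 / m2**1.5)


def intensity_features(img: VolumeImage, roi: np.ndarray) -> FeatureVector:
    """Peak / mean / median / skewness / COV within a ROI.

    Peak is the mean over in-ROI voxels whose centers lie inside a
    1 cm^3 sphere centered on the hottest ROI voxel (ties broken toward
    the lowest linear index); if the ROI clips the sphere, the mean is
    taken over the available voxels with a warning.
    """
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    vals = _values(img)
    grid = img.grid
    in_roi = vals[roi]

    flat = np.where(roi.ravel(), vals.ravel(), -np.inf)
    idx = int(np.argmax(flat))  # argmax returns the lowest index on ties
    kz, ky, kx = np.unravel_index(idx, vals.shape)
    X, Y, Z = grid.coordinate_grids()
    xs, ys, zs = grid.axis_centers()
    dist2 = (X - xs[kx]) ** 2 + (Y - ys[ky]) ** 2 + (Z - zs[kz]) ** 2
    sphere = dist2 <= PEAK_SPHERE_RADIUS_MM**2
    sel = sphere & roi
    if sphere.sum() > sel.sum():
        warnings.warn(
            "1 cm^3 peak sphere extends beyond the ROI; peak averaged over "
            f"{int(sel.sum())}/{int(sphere.sum())} voxels",
            stacklevel=2,
        )
    peak = float(vals[sel].mean())

    mean = float(in_roi.mean())
    return FeatureVector(
        peak=peak,
        mean=mean,
        median=float(np.median(in_roi)),
        skewness=_skewness(in_roi),
        cov=float(in_roi.std() / mean) if mean != 0 else float("nan"),
    )


def glcm_features(
    img: VolumeImage | np.ndarray,
    roi: np.ndarray,
    bin_width: float = 100.0,
) -> dict[str, float]:
    """GLCM texture features averaged over the four planar directions.

    Voxels are discretized to grey levels floor(v / bin_width) + 1
    (anchored at absolute 0, since the bin width is stated in absolute
    activity units).  Per transaxial slice, symmetric distance-1
    co-occurrence counts are accumulated for 0/45/90/135 degrees over
    pairs lying fully inside the ROI, pooled over slices per direction,
    normalized, and the five features are averaged over directions.
    """
    roi = np.asarray(roi, bool)
    vals = _values(img)
    if not roi.any():
        raise ValueError("empty ROI")
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[roi] = np.floor(np.maximum(vals[roi], 0.0) / bin_width).astype(np.int64) + 1
    n_levels = int(levels.max()) + 1
    if n_levels > 8192:
        raise ValueError(
            f"{n_levels} grey levels at bin width {bin_width}; increase the bin width"
        )

    counts = np.zeros((len(_GLCM_ANGLES), n_levels, n_levels))
    for z in range(levels.shape[0]):
        sl = levels[z]
        if not (sl > 0).any():
            continue
        c = graycomatrix(
            sl.astype(np.uint16 if n_levels <= 65535 else np.uint32),
            distances=[1],
            angles=list(_GLCM_ANGLES),
            levels=n_levels,
            symmetric=True,
        )
        counts += np.moveaxis(c[:, :, 0, :], -1, 0)
    counts = counts[:, 1:, 1:]  # drop pairs involving out-of-ROI (level 0)

    feats = {k: [] for k in FeatureVector.TEXTURE_NAMES}
    lev = np.arange(1, n_levels)
    I = lev[:, None]
    J = lev[None, :]
    skipped = 0
    for d in range(len(_GLCM_ANGLES)):
        tot = counts[d].sum()
        if tot == 0:
            skipped += 1
            continue
        p = counts[d] / tot
        pi = p.sum(axis=1)
        mu = float((lev * pi).sum())
        var = float(((lev - mu) ** 2 * pi).sum())
        feats["joint_average"].append(float((I * p).sum()))
        nz = p > 0
        feats["joint_entropy"].append(float(-(p[nz] * np.log2(p[nz])).sum()))
        feats["energy"].append(float((p**2).sum()))
        feats["homogeneity"].append(float((p / (1.0 + np.abs(I - J))).sum()))
        if var > 0:
            feats["correlation"].append(float((((I - mu) * (J - mu)) * p).sum() / var))
        else:
            feats["correlation"].append(1.0)  # constant ROI: perfectly correlated
    if skipped == len(_GLCM_ANGLES):
        raise ValueError("no in-ROI voxel pairs in any direction")
    if skipped:
        warnings.warn(f"{skipped} GLCM direction(s) had no in-ROI pairs; skipped", stacklevel=2)
    return {k: float(np.mean(v)) for k, v in feats.items()}


def all_features(
    img: VolumeImage, roi: np.ndarray, bin_width: float = 100.0
) -> FeatureVector:
    """Intensity plus texture features for one ROI."""
    fv = intensity_features(img, roi)
    for k, v in glcm_features(img, roi, bin_width).items():
        setattr(fv, k, v)
    return fv


@dataclass
class FeatureRegression:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    pearson_r: float
    n: int


def compare_features(x: np.ndarray, y: np.ndarray) -> FeatureRegression:
    """OLS y ~ x with t-based 95% CIs and the Pearson correlation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.var(x) == 0:
        raise ValueError("zero variance in x; regression undefined")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    return FeatureRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        pearson_r=float(res.rvalue),
        n=int(x.size),
    )


def nema_rois(
    grid: VoxelGrid,
    spec: PhantomSpec,
    annulus_inner_mm: float = 80.0,
    annulus_outer_mm: float = 95.0,
    n_background_slices: int = 5,
) -> RoiSet:
    """Exact sphere ROIs plus the background annulus of the NEMA analysis.

    Sphere masks collect voxel centers inside each true sphere (the
    nearest voxel is used if a sphere is smaller than the grid can
    resolve).  The background ROI is an annulus about the phantom axis
    on the sphere plane's slice and its +/-2 neighbours (5 slices);
    the default radii clear the sphere ring (57.2 + 18.5 mm = 75.7 mm)
    outward and stay inside the body shell (chamfer plane at -95.7 mm).
    """
    spheres = spec.spheres()
    if not spheres:
        raise ValueError("phantom spec contains no spheres")
    X, Y, Z = grid.coordinate_grids()
    xs, ys, zs = grid.axis_centers()
    rois = RoiSet(grid=grid)
    for s in spheres:
        cx, cy, cz = s.center
        (r,) = s.size
        mask = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r * r
        if not mask.any():
            kx = int(np.abs(xs - cx).argmin())
            ky = int(np.abs(ys - cy).argmin())
            kz = int(np.abs(zs - cz).argmin())
            mask = np.zeros(grid.shape, bool)
            mask[kz, ky, kx] = True
        rois.spheres[2 * r] = mask

    plane_z = spheres[0].center[2]
    kz = int(np.abs(zs - plane_z).argmin())
    half = n_background_slices // 2
    z_sel = np.arange(max(0, kz - half), min(grid.nz, kz + half + 1))
    r2 = X[0] ** 2 + Y[0] ** 2  # transaxial radius^2, (ny, nx)
    ann2d = (r2 >= annulus_inner_mm**2) & (r2 <= annulus_outer_mm**2)
    bg = np.zeros(grid.shape, bool)
    bg[z_sel] = ann2d
    for d, m in rois.spheres.items():
        if (bg & m).any():
            raise ValueError(
                f"background annulus intersects the {d:g} mm sphere ROI; "
                "adjust annulus radii"
            )
    rois.background = bg
    return rois
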