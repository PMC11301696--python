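"""File formats: NIfTI and raw-binary volumes, raw sinograms, run manifests.

The raw dialect is little-endian 32-bit float with x fastest, plus a
text header (``<base>.hdr``) documenting dimensions, voxel size,
origin, quantity and units.  NIfTI round trips go through nibabel with
a diagonal affine built from the voxel spacing and origin.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .geometry import ScannerGeometry, VoxelGrid, geometry_from_text, geometry_to_text
from .phantom import VolumeImage
from .projection import Sinogram

_QUANTITIES = {"activity", "attenuation", "reconstructed", "labels"}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_volume(img: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI (*.nii[.gz]) or raw float32 + text header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = img.grid
    if _is_nifti(path):
        affine = np.diag([g.dx, g.dy, g.dz, 1.0])
        affine[:3, 3] = g.origin
        # nibabel expects (x, y, z); internal layout is (z, y, x)
        data = np.asarray(img.values, np.float32).transpose(2, 1, 0)
        ni = nib.Nifti1Image(data, affine)
        ni.header["descrip"] = f"fastpet quantity={img.quantity}".encode()[:80]
        nib.save(ni, str(path))
        return path
    base = path.with_suffix("") if path.suffix in (".raw", ".hdr") else path
    raw = base.with_suffix(".raw")
    hdr = base.with_suffix(".hdr")
    np.asarray(img.values, "<f4").tofile(raw)
    lines = [
        f"nx: {g.nx}",
        f"ny: {g.ny}",
        f"nz: {g.nz}",
        f"dx_mm: {g.dx!r}",
        f"dy_mm: {g.dy!r}",
        f"dz_mm: {g.dz!r}",
        "origin_mm: " + ",".join(repr(v) for v in g.origin),
        f"quantity: {img.quantity}",
        "dtype: float32",
        "byteorder: little",
        "order: x-fastest",
    ]
    hdr.write_text("\n".join(lines) + "\n")
    return raw


def _parse_header(hdr: Path) -> dict[str, str]:
    out = {}
    for line in hdr.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        out[key.strip()] = val.strip()
    return out


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI or raw+header volume written by :func:`write_volume`."""
    path = Path(path)
    if _is_nifti(path):
        ni = nib.load(str(path))
        data = np.asanyarray(ni.dataobj).transpose(2, 1, 0).astype(np.float64)
        z = ni.affine
        grid = VoxelGrid(
            nx=data.shape[2],
            ny=data.shape[1],
            nz=data.shape[0],
            dx=float(abs(z[0, 0])),
            dy=float(abs(z[1, 1])),
            dz=float(abs(z[2, 2])),
            origin=tuple(float(v) for v in z[:3, 3]),
        )
        descrip = str(ni.header["descrip"].astype(str))
        quantity = "activity"
        for q in _QUANTITIES:
            if f"quantity={q}" in descrip:
                quantity = q
        return VolumeImage(data, grid, quantity)

    base = path.with_suffix("") if path.suffix in (".raw", ".hdr") else path
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    meta = _parse_header(hdr)
    grid = VoxelGrid(
        nx=int(meta["nx"]),
        ny=int(meta["ny"]),
        nz=int(meta["nz"]),
        dx=float(meta["dx_mm"]),
        dy=float(meta["dy_mm"]),
        dz=float(meta["dz_mm"]),
        origin=tuple(float(v) for v in meta["origin_mm"].split(",")),
    )
    expected = grid.nx * grid.ny * grid.nz * 4
    actual = raw.stat().st_size
    if actual != expected:
        raise ValueError(
            f"raw file size mismatch: header implies {expected} bytes, file has {actual}"
        )
    data = np.fromfile(raw, dtype="<f4").reshape(grid.shape).astype(np.float64)
    quantity = meta.get("quantity", "")
    if quantity not in _QUANTITIES:
        import warnings

        warnings.warn(f"unknown quantity {quantity!r}; defaulting to activity", stacklevel=2)
        quantity = "activity"
    return VolumeImage(data, grid, quantity)


def write_sinogram(s: Sinogram, grid: VoxelGrid | None, base: str | Path) -> Path:
    """Raw float32 sinogram (projection fastest, then view, plane, tof) + header."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    raw = base.with_suffix(".sraw")
    hdr = base.with_suffix(".shdr")
    v = s.values
    if s.tof:  # stored (tof, plane, view, projection) so projection stays fastest
        v = np.moveaxis(v, -1, 0)
    np.asarray(v, "<f4").tofile(raw)
    text = [
        f"tof: {int(s.tof)}",
        f"shape: {','.join(str(n) for n in s.values.shape)}",
        "# geometry follows",
        geometry_to_text(s.geometry, grid or _dummy_grid(s.geometry)),
    ]
    hdr.write_text("\n".join(text))
    return raw


def _dummy_grid(g: ScannerGeometry) -> VoxelGrid:
    return VoxelGrid(nx=1, ny=1, nz=1, dx=g.fov_transaxial_mm, dy=g.fov_transaxial_mm, dz=g.fov_axial_mm)


def read_sinogram(base: str | Path) -> Sinogram:
    base = Path(base)
    hdr = base.with_suffix(".shdr").read_text()
    head, _, geom_text = hdr.partition("# geometry follows\n")
    meta = {}
    for line in head.splitlines():
        k, _, v = line.partition(":")
        if v:
            meta[k.strip()] = v.strip()
    geom, _ = geometry_from_text(geom_text)
    tof = bool(int(meta["tof"]))
    shape = tuple(int(n) for n in meta["shape"].split(","))
    data = np.fromfile(base.with_suffix(".sraw"), dtype="<f4").astype(np.float64)
    if tof:
        stored = (shape[-1],) + shape[:-1]
        data = np.moveaxis(data.reshape(stored), 0, -1)
    else:
        data = data.reshape(shape)
    return Sinogram(data, geom, tof=tof)


@dataclass
class RunManifest:
    """Snapshot that fully determines a re-run (same platform numerics)."""

    command: str
    config: dict
    seeds: list[int]
    geometry_preset: str
    counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    software_version: str = __version__
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_json_default))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)
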