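"""Containers and file I/O for Hounsfield-unit volumes with voxel-spacing metadata.

Arrays are ordered ``(z, y, x)`` with ``z`` the cranio-caudal axis. Voxel
coordinates are 0-based and regions of interest are half-open boxes
``[lo, hi)``. Three on-disk containers are supported with a bit-exact
round trip on ``(data, spacing)``:

* NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel,
* MetaImage (``.mha`` / ``.mhd``) via SimpleITK,
* raw little-endian voxel data plus a JSON sidecar (``.raw`` + ``.json``).

HU values are validated against the CT scale ``[-1024, +3072]``. Spacing is
carried in micrometres internally and written to NIfTI/MetaImage headers in
millimetres, the convention third-party viewers expect.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

HU_MIN = -1024.0
HU_MAX = 3072.0

_AXES = ("z", "y", "x")


class DataError(ValueError):
    """Raised when an input file or volume violates a structural invariant."""


def _validate_spacing(spacing_um: Sequence[float]) -> tuple[float, float, float]:
    if len(spacing_um) != 3:
        raise DataError(f"spacing must have 3 entries (z, y, x), got {len(spacing_um)}")
    out = []
    for axis, s in zip(_AXES, spacing_um):
        s = float(s)
        if not np.isfinite(s) or s <= 0:
            raise DataError(f"voxel spacing must be finite and positive on axis {axis!r}, got {s}")
        out.append(s)
    return tuple(out)


@dataclasses.dataclass(frozen=True)
class Box:
    """Half-open, 0-based voxel box ``[lo, hi)`` in (z, y, x) order."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if len(lo) != 3 or len(hi) != 3:
            raise DataError("Box lo/hi must each have 3 entries (z, y, x)")
        if any(h < l for l, h in zip(lo, hi)):
            raise DataError(f"Box hi must be >= lo on every axis, got lo={lo}, hi={hi}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def clip(self, grid_shape: Sequence[int]) -> "Box":
        lo = tuple(min(max(l, 0), int(n)) for l, n in zip(self.lo, grid_shape))
        hi = tuple(min(max(h, 0), int(n)) for h, n in zip(self.hi, grid_shape))
        return Box(lo, hi)

    def dilate(self, margin: int, grid_shape: Sequence[int] | None = None) -> "Box":
        box = Box(tuple(l - margin for l in self.lo), tuple(h + margin for h in self.hi))
        return box.clip(grid_shape) if grid_shape is not None else box

    def within(self, grid_shape: Sequence[int]) -> bool:
        return all(l >= 0 and h <= int(n) for l, h, n in zip(self.lo, self.hi, grid_shape))

    def intersects(self, other: "Box") -> bool:
        return all(l1 < h2 and l2 < h1 for l1, h1, l2, h2 in zip(self.lo, self.hi, other.lo, other.hi))

    def to_dict(self) -> dict:
        return {"lo": list(self.lo), "hi": list(self.hi), "axis_order": "zyx", "half_open": True}

    @classmethod
    def from_dict(cls, d: dict) -> "Box":
        return cls(tuple(d["lo"]), tuple(d["hi"]))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Box":
        return cls.from_dict(json.loads(Path(path).read_text()))


def mask_from_box(box: Box, shape: Sequence[int]) -> np.ndarray:
    """Boolean array of ``shape`` that is True inside ``box``."""
    out = np.zeros(tuple(int(n) for n in shape), dtype=bool)
    out[box.clip(shape).slices] = True
    return out


@dataclasses.dataclass
class VoxelVolume:
    """A 3-D scalar grid of HU values with per-axis voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values, finite, within ``[-1024, +3072]``.
    spacing_um : (float, float, float)
        Voxel edge length per axis in micrometres, (z, y, x) order.
    origin_mm : (float, float, float)
        Physical offset of voxel (0, 0, 0), used to carry field-of-view
        offsets through split/stitch.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise DataError("volume data must be non-empty")
        if not np.isfinite(self.data).all():
            raise DataError("volume contains non-finite HU values")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise DataError(
                f"HU values outside [{HU_MIN:g}, {HU_MAX:g}]: observed range [{lo:g}, {hi:g}]"
            )
        self.spacing_um = _validate_spacing(self.spacing_um)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_um)) * 1e-9

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return VoxelVolume(data, self.spacing_um, self.origin_mm)


@dataclasses.dataclass
class Mask:
    """Binary grid sharing shape and spacing with its source volume."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool, copy=False)
        if self.data.ndim != 3:
            raise DataError(f"mask data must be 3-D, got ndim={self.data.ndim}")
        self.spacing_um = _validate_spacing(self.spacing_um)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_um)) * 1e-9

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


# ---------------------------------------------------------------------------
# format dispatch


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith(".raw"):
        return "raw"
    raise DataError(f"cannot infer volume format from file name {path.name!r} "
                    "(expected .nii[.gz], .mha/.mhd or .raw)")


def _storage_array(data: np.ndarray) -> np.ndarray:
    """Store integral HU losslessly as int16; keep floats otherwise."""
    if np.issubdtype(data.dtype, np.integer):
        return data.astype("<i2") if data.dtype.itemsize <= 2 else data.astype("<i4")
    if np.all(data == np.rint(data)):
        return np.rint(data).astype("<i2")
    return data.astype("<f4") if data.dtype == np.float32 else data.astype("<f8")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_nifti(arr, spacing_um, origin_mm, path: Path) -> None:
    sp_mm = np.asarray(spacing_um, dtype=float) / 1000.0
    affine = np.diag([sp_mm[0], sp_mm[1], sp_mm[2], 1.0])
    affine[:3, 3] = origin_mm
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(sp_mm))
    nib.save(img, str(path))


def _read_nifti(path: Path):
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    # zooms are float32 in the header; snap to 0.1 nm to undo cast noise
    spacing_um = tuple(round(float(z) * 1000.0, 4) for z in zooms)
    for axis, s in zip(_AXES, spacing_um):
        if s <= 0:
            raise DataError(f"NIfTI header of {path.name} has non-positive spacing on axis {axis!r}")
    data = np.asanyarray(img.dataobj)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, spacing_um, origin


def _write_metaimage(arr, spacing_um, origin_mm, path: Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(float(s) / 1000.0 for s in spacing_um[::-1]))
    img.SetOrigin(tuple(float(v) for v in origin_mm[::-1]))
    sitk.WriteImage(img, str(path))


def _read_metaimage(path: Path):
    img = sitk.ReadImage(str(path))
    spacing_um = tuple(float(s) * 1000.0 for s in img.GetSpacing()[::-1])
    for axis, s in zip(_AXES, spacing_um):
        if s <= 0:
            raise DataError(f"MetaImage header of {path.name} has non-positive spacing on axis {axis!r}")
    origin = tuple(float(v) for v in img.GetOrigin()[::-1])
    return sitk.GetArrayFromImage(img), spacing_um, origin


def _write_raw(arr, spacing_um, origin_mm, path: Path) -> None:
    arr = np.ascontiguousarray(arr)
    arr.tofile(path)
    sidecar = {
        "shape": list(arr.shape),
        "dtype": arr.dtype.str,
        "spacing_um": list(spacing_um),
        "origin_mm": list(origin_mm),
        "axis_order": "zyx",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")


def _read_raw(path: Path):
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise DataError(f"raw volume {path.name} has no JSON sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("shape", "dtype", "spacing_um"):
        if key not in meta:
            raise DataError(f"sidecar {sidecar_path.name} is missing required key {key!r}")
    arr = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    spacing_um = _validate_spacing(meta["spacing_um"])
    origin = tuple(float(v) for v in meta.get("origin_mm", (0.0, 0.0, 0.0)))
    return arr, spacing_um, origin


_WRITERS = {"nifti": _write_nifti, "metaimage": _write_metaimage, "raw": _write_raw}
_READERS = {"nifti": _read_nifti, "metaimage": _read_metaimage, "raw": _read_raw}


def write_volume(vol: VoxelVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume; the file round-trips bit-exactly through :func:`read_volume`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _WRITERS:
        raise DataError(f"unknown volume format {fmt!r}; expected one of {sorted(_WRITERS)}")
    _WRITERS[fmt](_storage_array(vol.data), vol.spacing_um, vol.origin_mm, path)
    return path


def read_volume(path: str | Path, format: str | None = None) -> VoxelVolume:
    """Read a volume with its spacing; a missing or zero spacing is a hard error."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _READERS:
        raise DataError(f"unknown volume format {fmt!r}; expected one of {sorted(_READERS)}")
    data, spacing_um, origin = _READERS[fmt](path)
    return VoxelVolume(data, spacing_um, origin)


def write_mask(mask: Mask, path: str | Path, format: str | None = None) -> Path:
    """Write a binary mask as an 8-bit volume in the same containers."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _WRITERS:
        raise DataError(f"unknown volume format {fmt!r}")
    _WRITERS[fmt](mask.data.astype(np.uint8), mask.spacing_um, mask.origin_mm, path)
    return path


def read_mask(path: str | Path, format: str | None = None) -> Mask:
    path = Path(path)
    if not path.exists():
        raise DataError(f"mask file not found: {path}")
    fmt = format or _infer_format(path)
    data, spacing_um, origin = _READERS[fmt](path)
    return Mask(data != 0, spacing_um, origin)
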