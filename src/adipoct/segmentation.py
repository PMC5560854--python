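"""Threshold segmentation of micro-CT volumes with fat-pad calibration.

The quantification method: smooth the reconstructed HU volume with a
Gaussian filter, segment the whole body with the closed band [-350, +3000]
HU, segment adipose tissue with a fat band whose lower bound is fixed at
-350 HU and whose upper bound is either the nominal -150 HU or calibrated
so that the segmented volume of an external fat pad of known mass matches
the volume implied by the fat density (0.92 g/mL). Because the pad boundary
suffers the same partial-volume blur as the fat depots inside the animal,
matching the pad volume transfers the correct fat/soft cut-off to the whole
scan and removes the operator from the threshold choice.

All thresholds are closed intervals on integer-quantised HU. The calibrated
upper bound is the smallest integer HU whose pad volume covers the
density-derived target; monotonicity of the pad volume in the upper bound
makes a bisection over integers exact.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .densitometry import FatDensity, mass_to_volume
from .volume_io import HU_MAX, HU_MIN, Box, DataError, Mask, VoxelVolume

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}

BODY_RANGE_DEFAULT = (-350.0, 3000.0)
FAT_RANGE_DEFAULT = (-350.0, -150.0)


@dataclasses.dataclass(frozen=True)
class HURange:
    """Closed HU interval [lo, hi] used as a segmentation band."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise DataError(f"HU range requires lo <= hi, got [{self.lo}, {self.hi}]")
        if self.lo < HU_MIN or self.hi > HU_MAX:
            raise DataError(f"HU range [{self.lo}, {self.hi}] outside [{HU_MIN:g}, {HU_MAX:g}]")

    def contains(self, data: np.ndarray) -> np.ndarray:
        return (data >= self.lo) & (data <= self.hi)


@dataclasses.dataclass(frozen=True)
class FatPadSpec:
    """The calibration reference: pad mass, fat density and its voxel ROI.

    The ROI is a half-open voxel box containing the pad (and possibly its
    support and surrounding air) but no animal tissue.
    """

    mass_g: float
    density: FatDensity
    roi: Box

    def __post_init__(self):
        if self.mass_g <= 0:
            raise DataError(f"fat pad mass must be positive, got {self.mass_g} g")

    @property
    def target_volume_mm3(self) -> float:
        return mass_to_volume(self.mass_g, self.density)


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the fat-threshold search against the pad reference."""

    fat_range: HURange
    achieved_pad_volume_mm3: float
    target_pad_volume_mm3: float
    iterations: int
    converged: bool  #: the search range could cover the target at all
    tolerance_mm3: float

    @property
    def residual_mm3(self) -> float:
        return self.achieved_pad_volume_mm3 - self.target_pad_volume_mm3

    @property
    def within_tolerance(self) -> bool:
        return abs(self.residual_mm3) <= self.tolerance_mm3


@dataclasses.dataclass(frozen=True)
class SegmentationResult:
    """A mask together with its exact voxel-count volume."""

    mask: Mask
    volume_mm3: float
    n_components_retained: int

    @classmethod
    def from_mask(cls, mask: Mask, n_components_retained: int = 0) -> "SegmentationResult":
        return cls(mask=mask, volume_mm3=mask.volume_mm3,
                   n_components_retained=n_components_retained)


# ---------------------------------------------------------------------------
# primitive operations


def gaussian_filter(vol: VoxelVolume, sigma_vox: float = 1.0) -> VoxelVolume:
    """Isotropic Gaussian noise filter (reflective boundaries); sigma 0 is identity."""
    if sigma_vox < 0:
        raise DataError(f"filter sigma must be non-negative, got {sigma_vox}")
    if sigma_vox == 0:
        return vol.with_data(vol.data.copy())
    data = ndimage.gaussian_filter(
        vol.data.astype(np.float32, copy=False), sigma=sigma_vox, mode="reflect"
    )
    return vol.with_data(data)


def threshold_mask(vol: VoxelVolume, hu_range: HURange) -> Mask:
    """Voxel is in the mask iff lo <= HU <= hi (closed interval)."""
    return Mask(hu_range.contains(vol.data), vol.spacing_um, vol.origin_mm)


@dataclasses.dataclass(frozen=True)
class ComponentLabels:
    """Connected components of a mask: labels start at 1, sizes sorted descending."""

    labels: np.ndarray
    sizes: np.ndarray  #: voxel counts, descending; sizes[i] belongs to label order[i]
    order: np.ndarray  #: original scipy labels sorted by decreasing size
    connectivity: int

    @property
    def n_components(self) -> int:
        return int(self.sizes.size)


def connected_components(mask: Mask, connectivity: int = 26) -> ComponentLabels:
    """Maximal connected sets under 6- or 26-connectivity."""
    if connectivity not in _STRUCTS:
        raise DataError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(mask.data, structure=_STRUCTS[connectivity])
    if n == 0:
        return ComponentLabels(labels, np.array([], dtype=np.int64),
                               np.array([], dtype=np.int64), connectivity)
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes, kind="stable")[::-1] + 1
    return ComponentLabels(labels, sizes[order - 1].astype(np.int64),
                           order.astype(np.int64), connectivity)


def largest_component(mask: Mask, connectivity: int = 6) -> Mask:
    comp = connected_components(mask, connectivity)
    if comp.n_components == 0:
        raise DataError("mask is empty; no connected component to retain")
    return Mask(comp.labels == comp.order[0], mask.spacing_um, mask.origin_mm)


def fill_cavities(mask: Mask) -> Mask:
    """Add fully enclosed cavities (e.g. lung interiors) to the mask."""
    return Mask(ndimage.binary_fill_holes(mask.data), mask.spacing_um, mask.origin_mm)


def _zero_rois(data: np.ndarray, rois: Sequence[Box | Mask | None]) -> np.ndarray:
    for roi in rois:
        if roi is None:
            continue
        if isinstance(roi, Mask):
            data &= ~roi.data
        else:
            data[roi.clip(data.shape).slices] = False
    return data


# ---------------------------------------------------------------------------
# body and fat segmentation


def segment_body(
    vol: VoxelVolume,
    body_range: HURange | tuple[float, float] = BODY_RANGE_DEFAULT,
    fat_pad_roi: Box | Mask | None = None,
    connectivity: int = 6,
    fill: bool = True,
) -> SegmentationResult:
    """Whole-body segmentation: threshold, exclude the pad ROI, keep the
    largest connected component and fill enclosed cavities so lung interiors
    count as body volume."""
    body_range = body_range if isinstance(body_range, HURange) else HURange(*body_range)
    raw = threshold_mask(vol, body_range)
    raw.data = _zero_rois(raw.data, [fat_pad_roi])
    if not raw.data.any():
        raise DataError("body mask is empty after thresholding")
    body = largest_component(raw, connectivity)
    if fill:
        body = fill_cavities(body)
    return SegmentationResult.from_mask(body, n_components_retained=1)


def segment_fat(
    vol: VoxelVolume,
    fat_range: HURange | tuple[float, float],
    body_mask: Mask,
    fat_pad_roi: Box | Mask | None = None,
    exclusion_rois: Sequence[Box | Mask] = (),
    surface_peel_vox: int = 0,
) -> SegmentationResult:
    """Adipose segmentation: fat band, restricted to the body mask, minus
    the pad ROI and any manual exclusion ROIs.

    ``surface_peel_vox > 0`` additionally restricts counting to the body
    core (the body mask eroded by that many voxels, 26-connectivity). The
    peel suppresses the skin/air partial-volume ring, where the blurred
    transition from air to soft tissue sweeps through the fat band — the
    same artifact class as the manual lung-area suppression, but at the
    body surface.
    """
    fat_range = fat_range if isinstance(fat_range, HURange) else HURange(*fat_range)
    if not body_mask.data.any():
        raise DataError("body mask is empty")
    if body_mask.shape != vol.shape:
        raise DataError("body mask shape does not match the volume")
    if surface_peel_vox < 0:
        raise DataError("surface peel must be non-negative")
    fat = threshold_mask(vol, fat_range)
    domain = body_mask.data
    if surface_peel_vox > 0:
        domain = ndimage.binary_erosion(domain, structure=_STRUCTS[26],
                                        iterations=surface_peel_vox)
    fat.data &= domain
    fat.data = _zero_rois(fat.data, [fat_pad_roi, *exclusion_rois])
    return SegmentationResult.from_mask(fat)


def lung_correction(fat_result: SegmentationResult, lung_roi: Box | Mask) -> SegmentationResult:
    """Manual lung-area suppression: remove fat voxels inside the lung ROI.

    The corrected volume is never larger than the input volume.
    """
    mask = fat_result.mask
    if isinstance(lung_roi, Box) and not lung_roi.clip(mask.shape).n_voxels and lung_roi.n_voxels:
        raise DataError("lung ROI lies outside the grid")
    corrected = Mask(mask.data.copy(), mask.spacing_um, mask.origin_mm)
    corrected.data = _zero_rois(corrected.data, [lung_roi])
    return SegmentationResult(
        mask=corrected,
        volume_mm3=corrected.volume_mm3,
        n_components_retained=fat_result.n_components_retained,
    )


def locate_fat_pad(
    vol: VoxelVolume,
    body_range: HURange | tuple[float, float] = BODY_RANGE_DEFAULT,
    connectivity: int = 26,
    margin_vox: int = 2,
) -> Box:
    """Fallback pad locator when no manual ROI is supplied.

    Returns the bounding box (plus margin) of the largest connected
    component of the body band that is disjoint from the animal (the
    largest component overall). 26-connectivity keeps small pads whole.
    """
    body_range = body_range if isinstance(body_range, HURange) else HURange(*body_range)
    comp = connected_components(threshold_mask(vol, body_range), connectivity)
    if comp.n_components < 2:
        raise DataError("no foreground component disjoint from the animal; "
                        "supply the fat-pad ROI manually")
    pad_label = comp.order[1]  # second-largest component
    idx = np.nonzero(comp.labels == pad_label)
    lo = tuple(int(i.min()) for i in idx)
    hi = tuple(int(i.max()) + 1 for i in idx)
    return Box(lo, hi).dilate(margin_vox, vol.shape)


# ---------------------------------------------------------------------------
# fat-pad threshold calibration


def pad_volume_at(vol: VoxelVolume, roi: Box, lo: float, hi: float) -> float:
    """Segmented pad volume (mm^3) inside the ROI for the band [lo, hi]."""
    sub = vol.data[roi.clip(vol.shape).slices]
    count = int(np.count_nonzero((sub >= lo) & (sub <= hi)))
    return count * vol.voxel_volume_mm3


def pad_volume_curve(vol: VoxelVolume, roi: Box, lo: float, his: Sequence[float]) -> np.ndarray:
    """Pad volume as a function of the upper bound (nondecreasing in hi)."""
    sub = vol.data[roi.clip(vol.shape).slices]
    above_lo = sub[sub >= lo]
    return np.array(
        [int(np.count_nonzero(above_lo <= hi)) for hi in his], dtype=float
    ) * vol.voxel_volume_mm3


def search_fat_threshold(
    vol: VoxelVolume,
    roi: Box,
    target_mm3: float,
    lo_fixed: float = -350.0,
    search: tuple[int, int] = (-349, 0),
    tol_mm3: float | None = None,
) -> CalibrationResult:
    """Smallest integer upper bound whose pad volume covers ``target_mm3``.

    Bisection over integer HU, valid because the pad volume is nondecreasing
    in the upper bound. If even the largest candidate under-covers the
    target, the result is flagged non-converged (never a silent success).
    """
    roi = roi.clip(vol.shape)
    if roi.n_voxels == 0:
        raise DataError("fat pad ROI is empty or outside the grid")
    if target_mm3 < 0:
        raise DataError("target pad volume must be non-negative")
    hi_min, hi_max = int(search[0]), int(search[1])
    if hi_min > hi_max:
        raise DataError(f"invalid search range [{hi_min}, {hi_max}]")
    if hi_min < lo_fixed:
        raise DataError("search range must start at or above the fixed lower bound")
    if tol_mm3 is None:
        tol_mm3 = max(0.01 * target_mm3, vol.voxel_volume_mm3)

    sub = vol.data[roi.slices]
    above_lo = sub[sub >= lo_fixed]

    def volume_at(hi: int) -> float:
        return int(np.count_nonzero(above_lo <= hi)) * vol.voxel_volume_mm3

    iterations = 1
    v_max = volume_at(hi_max)
    if v_max < target_mm3:
        return CalibrationResult(
            fat_range=HURange(lo_fixed, float(hi_max)),
            achieved_pad_volume_mm3=v_max,
            target_pad_volume_mm3=target_mm3,
            iterations=iterations,
            converged=False,
            tolerance_mm3=tol_mm3,
        )
    lo_i, hi_i = hi_min, hi_max  # invariant: volume_at(hi_i) >= target
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        iterations += 1
        if volume_at(mid) >= target_mm3:
            hi_i = mid
        else:
            lo_i = mid + 1
    achieved = volume_at(hi_i)
    return CalibrationResult(
        fat_range=HURange(lo_fixed, float(hi_i)),
        achieved_pad_volume_mm3=achieved,
        target_pad_volume_mm3=target_mm3,
        iterations=iterations + 1,
        converged=True,
        tolerance_mm3=tol_mm3,
    )


def calibrate_fat_threshold(
    vol: VoxelVolume,
    pad: FatPadSpec,
    lo_fixed: float = -350.0,
    search: tuple[int, int] = (-349, 0),
    tol_mm3: float | None = None,
) -> CalibrationResult:
    """Calibrate the upper fat bound against the pad's density-derived volume."""
    target = pad.target_volume_mm3
    roi_volume = pad.roi.clip(vol.shape).n_voxels * vol.voxel_volume_mm3
    if target > roi_volume:
        return CalibrationResult(
            fat_range=HURange(lo_fixed, float(int(search[1]))),
            achieved_pad_volume_mm3=pad_volume_at(vol, pad.roi, lo_fixed, search[1]),
            target_pad_volume_mm3=target,
            iterations=1,
            converged=False,
            tolerance_mm3=tol_mm3 if tol_mm3 is not None else 0.01 * target,
        )
    return search_fat_threshold(vol, pad.roi, target, lo_fixed, search, tol_mm3)


# ---------------------------------------------------------------------------
# field-of-view stitching


def stitch(fovs: Sequence[VoxelVolume], overlap_vox: int | None = None) -> VoxelVolume:
    """Reassemble overlapping axial fields of view into one whole-body volume.

    Non-overlap regions are copied exactly; overlap regions are averaged.
    FOV offsets are read from ``origin_mm``; a gap between consecutive FOVs
    is an error.
    """
    if len(fovs) == 0:
        raise DataError("no fields of view to stitch")
    spacing = fovs[0].spacing_um
    dz_mm = spacing[0] / 1000.0
    for f in fovs:
        if f.spacing_um != spacing:
            raise DataError("fields of view disagree in voxel spacing")
        if f.shape[1:] != fovs[0].shape[1:]:
            raise DataError("fields of view disagree in (y, x) shape")
    base_z = min(f.origin_mm[0] for f in fovs)
    items = []
    for f in fovs:
        off = (f.origin_mm[0] - base_z) / dz_mm
        off_i = int(round(off))
        if abs(off - off_i) > 1e-6:
            raise DataError("field-of-view offset is not an integer number of slices")
        items.append((off_i, f))
    items.sort(key=lambda t: t[0])

    end = 0
    for off_i, f in items:
        if off_i > end:
            raise DataError(f"gap between fields of view at slice {end}")
        end = max(end, off_i + f.shape[0])

    nz = end
    shape = (nz,) + fovs[0].shape[1:]
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int32)
    for off_i, f in items:
        acc[off_i:off_i + f.shape[0]] += f.data
        cnt[off_i:off_i + f.shape[0]] += 1
    data = (acc / cnt).astype(np.float32)
    origin = (base_z, fovs[0].origin_mm[1], fovs[0].origin_mm[2])
    return VoxelVolume(data, spacing, origin)
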