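"""End-to-end fat quantification as a scikit-learn-style estimator.

``FatQuantificationPipeline.fit`` takes one HU volume and runs the full
method — Gaussian filtering, fat-pad threshold calibration, whole-body /
fat / lean segmentation, composition — storing the results as fitted
attributes. ``predict`` applies the fitted (calibrated) fat band to another
volume, which is how a threshold calibrated on one scan is reused on a
repeat scan of the same setup (e.g. the gated/ungated comparison).
"""

from __future__ import annotations

from typing import Sequence

from sklearn.base import BaseEstimator

from .composition import BodyComposition, compute_composition
from .segmentation import (
    BODY_RANGE_DEFAULT,
    FAT_RANGE_DEFAULT,
    CalibrationResult,
    FatPadSpec,
    HURange,
    SegmentationResult,
    calibrate_fat_threshold,
    gaussian_filter,
    lung_correction,
    segment_body,
    segment_fat,
)
from .volume_io import Box, DataError, Mask, VoxelVolume

LEAN_HI_DEFAULT = 300.0


class FatQuantificationPipeline(BaseEstimator):
    """Calibrated Hounsfield-threshold body-composition estimator.

    Parameters
    ----------
    pad_spec : FatPadSpec or None
        Calibration reference (pad mass, fat density, ROI). Required when
        ``calibrate`` is True.
    calibrate : bool
        If True, the upper fat bound is searched so the segmented pad volume
        matches the density-derived pad volume; otherwise ``fat_range`` is
        used verbatim.
    fat_range, body_range : (lo, hi)
        Closed HU bands; defaults (-350, -150) and (-350, +3000).
    lean_lo, lean_hi : float or None
        Lean band; ``lean_lo=None`` starts the lean band one HU above the
        (possibly calibrated) fat band so the bands abut without overlap.
    filter_sigma_vox : float
        Noise-filter width in voxels.
    body_connectivity : int
        6 or 26, for the largest-component body extraction.
    lung_roi : Box or Mask or None
        Optional manual lung-area suppression applied to the fat mask.
    exclusion_rois : sequence of Box or Mask
        Additional manual exclusions applied to fat and lean masks.
    search : (int, int)
        Integer HU search range for the calibrated upper fat bound.
    tol_mm3 : float or None
        Calibration residual tolerance; default 1% of the target volume.
    surface_peel_vox : int
        Restrict adipose counting to the body mask eroded by this many
        voxels, suppressing the skin/air partial-volume ring (0 disables).

    Attributes
    ----------
    fat_range_ : HURange
        The band actually used for fat segmentation.
    calibration_ : CalibrationResult or None
    body_, fat_, lean_ : SegmentationResult
    composition_ : BodyComposition
    filtered_ : VoxelVolume
    """

    def __init__(
        self,
        pad_spec: FatPadSpec | None = None,
        calibrate: bool = True,
        fat_range: tuple[float, float] = FAT_RANGE_DEFAULT,
        body_range: tuple[float, float] = BODY_RANGE_DEFAULT,
        lean_lo: float | None = None,
        lean_hi: float = LEAN_HI_DEFAULT,
        filter_sigma_vox: float = 1.0,
        body_connectivity: int = 6,
        lung_roi: Box | Mask | None = None,
        exclusion_rois: Sequence[Box | Mask] = (),
        search: tuple[int, int] = (-349, 0),
        tol_mm3: float | None = None,
        surface_peel_vox: int = 2,
    ):
        self.pad_spec = pad_spec
        self.calibrate = calibrate
        self.fat_range = fat_range
        self.body_range = body_range
        self.lean_lo = lean_lo
        self.lean_hi = lean_hi
        self.filter_sigma_vox = filter_sigma_vox
        self.body_connectivity = body_connectivity
        self.lung_roi = lung_roi
        self.exclusion_rois = exclusion_rois
        self.search = search
        self.tol_mm3 = tol_mm3
        self.surface_peel_vox = surface_peel_vox

    # -- estimator API ------------------------------------------------

    def fit(self, X: VoxelVolume, y=None) -> "FatQuantificationPipeline":
        """Run the full quantification on one volume."""
        if not isinstance(X, VoxelVolume):
            raise DataError("X must be a VoxelVolume")
        vol = gaussian_filter(X, self.filter_sigma_vox)
        self.filtered_ = vol

        pad_roi = self.pad_spec.roi if self.pad_spec is not None else None
        if self.calibrate:
            if self.pad_spec is None:
                raise DataError("calibration requested but no pad_spec given "
                                "(pass calibrate=False to use the nominal fat band)")
            cal = calibrate_fat_threshold(
                vol, self.pad_spec, lo_fixed=self.fat_range[0],
                search=self.search, tol_mm3=self.tol_mm3,
            )
            if not cal.converged:
                raise DataError(
                    "fat-threshold calibration did not converge: pad volume at the "
                    f"top of the search range is {cal.achieved_pad_volume_mm3:.2f} mm^3 "
                    f"against a target of {cal.target_pad_volume_mm3:.2f} mm^3"
                )
            self.calibration_: CalibrationResult | None = cal
            self.fat_range_ = cal.fat_range
        else:
            self.calibration_ = None
            self.fat_range_ = HURange(*self.fat_range)

        self.body_ = segment_body(
            vol, HURange(*self.body_range), fat_pad_roi=pad_roi,
            connectivity=self.body_connectivity,
        )
        fat = segment_fat(vol, self.fat_range_, self.body_.mask,
                          fat_pad_roi=pad_roi, exclusion_rois=self.exclusion_rois,
                          surface_peel_vox=self.surface_peel_vox)
        if self.lung_roi is not None:
            fat = lung_correction(fat, self.lung_roi)
        self.fat_ = fat

        lean_lo = self.lean_lo if self.lean_lo is not None else self.fat_range_.hi + 1.0
        lean_rois = list(self.exclusion_rois)
        if self.lung_roi is not None:
            lean_rois.append(self.lung_roi)
        self.lean_ = segment_fat(vol, HURange(lean_lo, self.lean_hi), self.body_.mask,
                                 fat_pad_roi=pad_roi, exclusion_rois=lean_rois)
        self.composition_ = compute_composition(self.body_, self.fat_, self.lean_)
        return self

    def predict(self, X: VoxelVolume) -> Mask:
        """Fat mask of a new volume under the fitted fat band."""
        self._check_fitted()
        vol = gaussian_filter(X, self.filter_sigma_vox)
        pad_roi = self.pad_spec.roi if self.pad_spec is not None else None
        body = segment_body(vol, HURange(*self.body_range), fat_pad_roi=pad_roi,
                            connectivity=self.body_connectivity)
        fat = segment_fat(vol, self.fat_range_, body.mask,
                          fat_pad_roi=pad_roi, exclusion_rois=self.exclusion_rois,
                          surface_peel_vox=self.surface_peel_vox)
        if self.lung_roi is not None:
            fat = lung_correction(fat, self.lung_roi)
        return fat.mask

    def fit_quantify(self, X: VoxelVolume) -> BodyComposition:
        """Convenience: fit on a volume and return its composition."""
        return self.fit(X).composition_

    def _check_fitted(self) -> None:
        if not hasattr(self, "fat_range_"):
            raise DataError("this pipeline is not fitted yet; call fit first")
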