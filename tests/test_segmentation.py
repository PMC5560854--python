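"""Segmentation primitives, fat-pad calibration and stitching.

The calibration tests use an exhaustive integer-HU sweep implemented
independently (plain numpy counting) as the oracle for the bisection.
"""

from __future__ import annotations

import numpy as np
import pytest

from adipoct.densitometry import FatDensity
from adipoct.phantom import (
    BODY_LABELS,
    FAT_SC,
    FAT_VISC,
    PhantomSpec,
    fat_pad_spec,
    generate_phantom,
    split_fields_of_view,
)
from adipoct.segmentation import (
    CalibrationResult,
    FatPadSpec,
    HURange,
    calibrate_fat_threshold,
    connected_components,
    gaussian_filter,
    locate_fat_pad,
    lung_correction,
    pad_volume_curve,
    search_fat_threshold,
    segment_body,
    segment_fat,
    stitch,
    threshold_mask,
)
from adipoct.volume_io import Box, DataError, Mask, VoxelVolume

SP100 = (100.0, 100.0, 100.0)


def _vol(data):
    return VoxelVolume(np.asarray(data, dtype=np.float32), SP100)


# ---------------------------------------------------------------------------
# gaussian filter


def test_filter_sigma_zero_is_identity(phantom_small):
    out = gaussian_filter(phantom_small.volume, 0.0)
    np.testing.assert_array_equal(out.data, phantom_small.volume.data)


def test_filter_constant_volume_unchanged():
    vol = _vol(np.full((12, 12, 12), 40.0))
    np.testing.assert_allclose(gaussian_filter(vol, 2.0).data, 40.0, atol=1e-3)


def test_filter_preserves_impulse_mass():
    data = np.zeros((21, 21, 21), dtype=np.float32)
    data[10, 10, 10] = 1000.0
    out = gaussian_filter(_vol(data), 1.0)
    assert out.data.sum() == pytest.approx(1000.0, rel=1e-4)


def test_filter_rejects_negative_sigma(phantom_small):
    with pytest.raises(DataError):
        gaussian_filter(phantom_small.volume, -0.5)


# ---------------------------------------------------------------------------
# thresholding and connected components


def test_threshold_closed_interval_membership():
    vol = _vol([[[-400.0, -350.0, -250.0, -150.0, -100.0]]])
    mask = threshold_mask(vol, HURange(-350, -150))
    np.testing.assert_array_equal(mask.data[0, 0], [False, True, True, True, False])


def test_threshold_universal_band_selects_everything(phantom_small):
    mask = threshold_mask(phantom_small.volume, HURange(-1024, 3072))
    assert mask.data.all()


def test_threshold_on_noiseless_phantom_matches_labels(phantom_small_noiseless):
    """Body band [-350, +3000] selects exactly the non-air, non-lung-interior
    material (soft, fat, bone, pad, bed) on a noiseless phantom."""
    ph = phantom_small_noiseless
    mask = threshold_mask(ph.volume, HURange(-350, 3000))
    expected = ~np.isin(ph.labels.labels, [0, 1])  # air, lung
    np.testing.assert_array_equal(mask.data, expected)


def test_connected_components_two_cubes():
    data = np.zeros((10, 10, 10), dtype=bool)
    data[1:3, 1:3, 1:3] = True
    data[6:9, 6:9, 6:9] = True
    comp = connected_components(Mask(data, SP100), 6)
    assert comp.n_components == 2
    assert list(comp.sizes) == [27, 8]


def test_connected_components_empty_mask():
    comp = connected_components(Mask(np.zeros((4, 4, 4), bool), SP100), 26)
    assert comp.n_components == 0


def test_diagonal_pair_splits_under_6_connectivity():
    data = np.zeros((4, 4, 4), dtype=bool)
    data[1, 1, 1] = data[2, 2, 1] = True  # edge-diagonal neighbours
    assert connected_components(Mask(data, SP100), 26).n_components == 1
    assert connected_components(Mask(data, SP100), 6).n_components == 2


# ---------------------------------------------------------------------------
# body segmentation


def test_body_volume_of_solid_box_is_exact():
    data = np.full((30, 30, 30), -1000.0, dtype=np.float32)
    data[5:25, 5:17, 5:15] = 40.0  # 20 x 12 x 10 voxels
    res = segment_body(_vol(data))
    assert res.volume_mm3 == pytest.approx(20 * 12 * 10 * 0.001, abs=1e-12)


def test_body_volume_counts_enclosed_cavities():
    data = np.full((30, 30, 30), -1000.0, dtype=np.float32)
    data[5:25, 5:25, 5:25] = 40.0
    data[10:15, 10:15, 10:15] = -700.0  # lung-like cavity
    res = segment_body(_vol(data))
    assert res.volume_mm3 == pytest.approx(20 ** 3 * 0.001, abs=1e-12)


def test_body_volume_close_to_ground_truth(phantom_default, pad_default):
    """On the default phantom (noise 25 HU) the body volume is within 3% of
    the ground-truth body-label volume."""
    vol = gaussian_filter(phantom_default.volume, 1.0)
    res = segment_body(vol, fat_pad_roi=pad_default.roi)
    truth = phantom_default.truth.body_volume_mm3
    assert abs(res.volume_mm3 - truth) / truth <= 0.03


def test_body_volume_unaffected_by_external_pad(phantom_small):
    """Removing the pad (air in its ROI) leaves the body volume unchanged."""
    ph = phantom_small
    roi = ph.truth.pad_roi
    vol = gaussian_filter(ph.volume, 1.0)
    with_pad = segment_body(vol, fat_pad_roi=roi)
    scrubbed = vol.data.copy()
    scrubbed[ph.truth.bed_box.slices] = -1000.0
    without_pad = segment_body(vol.with_data(scrubbed), fat_pad_roi=roi)
    assert with_pad.volume_mm3 == without_pad.volume_mm3


def test_empty_body_mask_is_an_error():
    with pytest.raises(DataError, match="empty"):
        segment_body(_vol(np.full((8, 8, 8), -1000.0)))


def test_fallback_pad_locator_finds_the_pad(phantom_small):
    """Without a manual ROI, the largest non-animal component is the pad
    block; its box contains every pad voxel and no animal tissue."""
    ph = phantom_small
    vol = gaussian_filter(ph.volume, 1.0)
    roi = locate_fat_pad(vol)
    from adipoct.phantom import BODY_LABELS, FAT_PAD

    pad_voxels = np.argwhere(ph.labels.labels == FAT_PAD)
    assert (pad_voxels >= roi.lo).all() and (pad_voxels < roi.hi).all()
    assert not np.isin(ph.labels.labels[roi.slices], BODY_LABELS).any()


def test_fallback_pad_locator_errors_without_a_pad():
    data = np.full((20, 20, 20), -1000.0, dtype=np.float32)
    data[5:15, 5:15, 5:15] = 40.0
    with pytest.raises(DataError, match="manual"):
        locate_fat_pad(_vol(data))


# ---------------------------------------------------------------------------
# calibration


def _pad_in_soft_block(pad_hu=-250.0):
    """Noiseless pad: an HU plateau inside a soft block; no blur."""
    data = np.full((24, 24, 24), 40.0, dtype=np.float32)
    data[8:16, 8:16, 8:16] = pad_hu  # 512 voxels
    vol = _vol(data)
    roi = Box((4, 4, 4), (20, 20, 20))
    return vol, roi, 512 * vol.voxel_volume_mm3


def test_noiseless_pad_calibrates_to_the_plateau():
    """Every pad voxel at -250 HU and an exact target give hi = -250
    (smallest covering threshold)."""
    vol, roi, target = _pad_in_soft_block()
    res = search_fat_threshold(vol, roi, target)
    assert res.converged
    assert res.fat_range == HURange(-350.0, -250.0)
    assert res.residual_mm3 == 0.0


def test_zero_target_returns_search_minimum():
    vol, roi, _ = _pad_in_soft_block()
    res = search_fat_threshold(vol, roi, 0.0, search=(-349, 0))
    assert res.converged and res.fat_range.hi == -349.0


def test_unreachable_target_is_flagged_not_silent():
    vol, roi, target = _pad_in_soft_block()
    res = search_fat_threshold(vol, roi, target * 100, search=(-349, -200))
    assert not res.converged


def test_oversized_target_flagged_by_calibrate():
    vol, roi, _ = _pad_in_soft_block()
    pad = FatPadSpec(mass_g=10.0, density=FatDensity(0.92), roi=roi)
    res = calibrate_fat_threshold(vol, pad)
    assert not res.converged


def test_empty_roi_is_an_error():
    vol, _, _ = _pad_in_soft_block()
    with pytest.raises(DataError, match="ROI"):
        search_fat_threshold(vol, Box((0, 0, 0), (0, 0, 0)), 1.0)


def _sweep_oracle(vol, roi, target, lo=-350.0, search=(-349, 0)):
    """Independent exhaustive sweep over every integer upper bound."""
    sub = vol.data[roi.slices]
    for hi in range(search[0], search[1] + 1):
        v = np.count_nonzero((sub >= lo) & (sub <= hi)) * vol.voxel_volume_mm3
        if v >= target:
            return float(hi)
    return None


def test_noisy_pad_bisection_equals_exhaustive_sweep(phantom_small):
    ph = phantom_small
    pad = fat_pad_spec(ph.truth)
    vol = gaussian_filter(ph.volume, 1.0)
    res = calibrate_fat_threshold(vol, pad)
    assert res.converged
    expected = _sweep_oracle(vol, pad.roi.clip(vol.shape), pad.target_volume_mm3)
    assert res.fat_range.hi == expected


def test_pad_volume_is_nondecreasing_in_hi(phantom_small):
    ph = phantom_small
    pad = fat_pad_spec(ph.truth)
    vol = gaussian_filter(ph.volume, 1.0)
    his = np.arange(-349, 1)
    curve = pad_volume_curve(vol, pad.roi.clip(vol.shape), -350.0, his)
    assert (np.diff(curve) >= 0).all()


# ---------------------------------------------------------------------------
# fat segmentation


def test_fat_volume_recovered_within_2pp(phantom_default, pad_default):
    """Calibrated fat volume as a fraction of body volume matches truth
    within 2 percentage points (noise 25 HU, no motion)."""
    ph = phantom_default
    vol = gaussian_filter(ph.volume, 1.0)
    cal = calibrate_fat_threshold(vol, pad_default)
    body = segment_body(vol, fat_pad_roi=pad_default.roi)
    fat = segment_fat(vol, cal.fat_range, body.mask, fat_pad_roi=pad_default.roi,
                      surface_peel_vox=2)
    estimated = fat.volume_mm3 / body.volume_mm3
    assert abs(estimated - ph.truth.true_fat_fraction) <= 0.02


def test_degenerate_band_with_no_matching_voxel_is_empty(phantom_small):
    ph = phantom_small
    body = segment_body(ph.volume, fat_pad_roi=ph.truth.pad_roi)
    data = ph.volume.data.copy()
    data[data == -350.0] = -349.0
    fat = segment_fat(ph.volume.with_data(data), HURange(-350, -350), body.mask)
    assert fat.volume_mm3 == 0.0


def test_exclusion_roi_removes_exactly_the_enclosed_fat(phantom_small_noiseless):
    """On a noiseless phantom, excluding a box covering all visceral fat
    lowers the fat volume by exactly the visceral voxels in the body mask."""
    ph = phantom_small_noiseless
    body = segment_body(ph.volume, fat_pad_roi=ph.truth.pad_roi)
    visc = ph.labels.labels == FAT_VISC
    idx = np.nonzero(visc)
    roi = Box(tuple(int(i.min()) for i in idx), tuple(int(i.max()) + 1 for i in idx))
    base = segment_fat(ph.volume, HURange(-350, -150), body.mask,
                       fat_pad_roi=ph.truth.pad_roi)
    excl = segment_fat(ph.volume, HURange(-350, -150), body.mask,
                       fat_pad_roi=ph.truth.pad_roi, exclusion_rois=[roi])
    removed_mask = base.mask.data & ~excl.mask.data
    expected = base.mask.data[roi.slices].sum()
    assert removed_mask.sum() == expected
    assert (base.volume_mm3 - excl.volume_mm3) == pytest.approx(
        expected * ph.volume.voxel_volume_mm3, abs=1e-12
    )


def test_mask_volume_is_exact_voxel_multiple(phantom_small):
    ph = phantom_small
    body = segment_body(ph.volume, fat_pad_roi=ph.truth.pad_roi)
    v = ph.volume.voxel_volume_mm3
    assert body.volume_mm3 / v == pytest.approx(round(body.volume_mm3 / v), abs=1e-9)


# ---------------------------------------------------------------------------
# lung correction


def _fat_result(phantom):
    body = segment_body(phantom.volume, fat_pad_roi=phantom.truth.pad_roi)
    return segment_fat(phantom.volume, HURange(-350, -150), body.mask,
                       fat_pad_roi=phantom.truth.pad_roi)


def test_lung_roi_disjoint_from_mask_changes_nothing(phantom_small):
    fat = _fat_result(phantom_small)
    out = lung_correction(fat, Box((0, 0, 0), (1, 1, 1)))
    assert out.volume_mm3 == fat.volume_mm3


def test_lung_roi_covering_grid_empties_the_mask(phantom_small):
    fat = _fat_result(phantom_small)
    out = lung_correction(fat, Box((0, 0, 0), phantom_small.volume.shape))
    assert out.volume_mm3 == 0.0


def test_lung_correction_never_increases_volume(phantom_small):
    fat = _fat_result(phantom_small)
    out = lung_correction(fat, phantom_small.truth.lung_roi)
    assert out.volume_mm3 <= fat.volume_mm3


# ---------------------------------------------------------------------------
# stitching


def test_split_then_stitch_is_exact(phantom_small):
    vol = phantom_small.volume
    fovs = split_fields_of_view(vol, 3, 10)
    out = stitch(fovs)
    np.testing.assert_array_equal(out.data, vol.data)


def test_two_fovs_zero_overlap_concatenate():
    data = np.arange(20 * 4 * 4, dtype=np.float32).reshape(20, 4, 4)
    vol = VoxelVolume(data, SP100)
    out = stitch(split_fields_of_view(vol, 2, 0))
    np.testing.assert_array_equal(out.data, data)


def test_overlap_disagreement_is_averaged():
    a = VoxelVolume(np.full((10, 4, 4), -1000.0, np.float32), SP100)
    b = VoxelVolume(np.full((10, 4, 4), -990.0, np.float32), SP100,
                    origin_mm=(0.5, 0.0, 0.0))  # 5-slice overlap
    out = stitch([a, b])
    np.testing.assert_array_equal(out.data[:5], -1000.0)
    np.testing.assert_array_equal(out.data[5:10], -995.0)
    np.testing.assert_array_equal(out.data[10:], -990.0)


def test_gap_between_fovs_is_rejected():
    a = VoxelVolume(np.zeros((5, 4, 4), np.float32), SP100)
    b = VoxelVolume(np.zeros((5, 4, 4), np.float32), SP100, origin_mm=(0.8, 0.0, 0.0))
    with pytest.raises(DataError, match="gap"):
        stitch([a, b])
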