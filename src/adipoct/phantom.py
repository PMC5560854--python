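"""Synthetic mouse-like micro-CT phantoms with known tissue composition.

A phantom is a (z, y, x) HU grid emulating a whole-body mouse acquisition at
100 um isotropic voxels: air background, an ellipsoidal body of soft tissue
containing two lung ellipsoids, a dorsal bone rod, compact subcutaneous and
visceral fat depots, and — dorsal to the animal — an excised fat pad of known
mass embedded in a small tissue-equivalent support block, as used to anchor
threshold calibration. The ideal per-tissue HU field is blurred by a Gaussian
point-spread function (partial-volume effect), optionally motion-blurred
along the cranio-caudal axis (ungated breathing), and corrupted by Gaussian
noise. Every voxel carries exactly one ground-truth label, so downstream
segmentation accuracy can be scored exactly.

Fat depots are deliberately compact blobs buried >=0.5 mm under the surface
rather than a thin subcutaneous shell: at desk-scale grids a sub-voxel shell
would be erased by the point-spread blur, which would test the blur rather
than the segmentation.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .densitometry import DEFAULT_FAT_DENSITY, FatDensity
from .volume_io import Box, DataError, VoxelVolume

# ground-truth label codes
AIR, LUNG, SOFT, FAT_SC, FAT_VISC, BONE, FAT_PAD, BED = range(8)
LABEL_NAMES = {
    AIR: "air",
    LUNG: "lung",
    SOFT: "soft",
    FAT_SC: "fat_sc",
    FAT_VISC: "fat_visc",
    BONE: "bone",
    FAT_PAD: "fat_pad",
    BED: "bed",
}
#: labels whose voxels count as "the animal" for ground-truth fractions
BODY_LABELS = (LUNG, SOFT, FAT_SC, FAT_VISC, BONE)


@dataclasses.dataclass(frozen=True)
class TissueModel:
    """Mean HU per tissue class; noise SD comes from the phantom spec.

    Defaults put fat inside the paper-reported fat band [-350, -150] HU and
    every other class outside it.
    """

    air: float = -1000.0
    lung: float = -700.0
    fat: float = -250.0
    soft: float = 40.0
    bone: float = 1000.0

    def __post_init__(self):
        if not (-350.0 <= self.fat <= -150.0):
            raise DataError(f"fat mean HU must lie in [-350, -150], got {self.fat}")
        if self.soft <= -150.0:
            raise DataError(f"soft-tissue mean HU must exceed -150, got {self.soft}")
        if self.air >= -350.0 or self.lung >= -350.0:
            raise DataError("air and lung mean HU must lie below -350")

    def lookup(self) -> np.ndarray:
        """HU mean per label code; the pad is pure fat, the bed soft-equivalent."""
        return np.array(
            [self.air, self.lung, self.soft, self.fat, self.fat, self.bone, self.fat, self.soft],
            dtype=np.float32,
        )


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic scan.

    Geometry fields left at ``None`` are derived from the grid so that the
    layout (body, pad, support, lungs) scales with grid size. All arrays are
    (z, y, x) ordered with z cranio-caudal.
    """

    grid_shape: tuple[int, int, int] = (160, 112, 112)
    voxel_spacing_um: tuple[float, float, float] = (100.0, 100.0, 100.0)
    body_axes_mm: tuple[float, float, float] | None = None
    fat_fraction_target: float = 0.20
    lung_volume_mm3: float | None = None
    bone_fraction: float = 0.05
    fat_pad_mass_g: float | None = None
    sc_fat_share: float = 0.55
    depot_burial_mm: float = 0.5
    noise_sd_hu: float = 25.0
    psf_sigma_vox: float = 0.4
    motion_sigma_vox: float = 0.0
    seed: int = 0
    tissue: TissueModel = TissueModel()
    fat_density: FatDensity = DEFAULT_FAT_DENSITY

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise DataError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        for s in self.voxel_spacing_um:
            if s <= 0:
                raise DataError("voxel spacing must be positive")
        if not (0.0 < self.fat_fraction_target < 0.6):
            raise DataError(f"fat_fraction_target must lie in (0, 0.6), got {self.fat_fraction_target}")
        if not (0.0 <= self.bone_fraction < 0.5):
            raise DataError(f"bone_fraction must lie in [0, 0.5), got {self.bone_fraction}")
        if not (0.0 < self.sc_fat_share < 1.0):
            raise DataError("sc_fat_share must lie in (0, 1)")
        if self.depot_burial_mm < 0:
            raise DataError("depot_burial_mm must be non-negative")
        if self.noise_sd_hu < 0 or self.psf_sigma_vox < 0 or self.motion_sigma_vox < 0:
            raise DataError("noise/blur sigmas must be non-negative")
        if self.lung_volume_mm3 is not None and self.lung_volume_mm3 <= 0:
            raise DataError("lung_volume_mm3 must be positive")
        if self.fat_pad_mass_g is not None and self.fat_pad_mass_g <= 0:
            raise DataError("fat_pad_mass_g must be positive")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s / 1000.0 for n, s in zip(self.grid_shape, self.voxel_spacing_um))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_um)) * 1e-9


@dataclasses.dataclass
class LabelVolume:
    """Per-voxel ground-truth tissue labels paired with a phantom volume."""

    labels: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError("label volume must be 3-D")
        if self.labels.min() < 0 or self.labels.max() > BED:
            raise DataError("labels outside the known label set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)


@dataclasses.dataclass
class GroundTruth:
    """Exact per-label voxel counts and volumes for one phantom."""

    voxel_counts: dict[str, int]
    volumes_mm3: dict[str, float]
    true_fat_fraction: float
    fat_pad_volume_mm3: float
    fat_pad_mass_g: float
    voxel_volume_mm3: float
    pad_roi: Box
    lung_roi: Box
    bed_box: Box

    def __post_init__(self):
        if not (0.0 < self.true_fat_fraction < 1.0):
            raise DataError(f"true fat fraction must lie in (0, 1), got {self.true_fat_fraction}")

    @property
    def body_volume_mm3(self) -> float:
        return sum(self.volumes_mm3[LABEL_NAMES[c]] for c in BODY_LABELS)


class Phantom(NamedTuple):
    volume: VoxelVolume
    labels: LabelVolume
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry helpers


def _coord_grids_mm(shape, spacing_um):
    """Open (z, y, x) coordinate grids in mm at voxel centres."""
    return [
        ((np.arange(n, dtype=np.float64) + 0.5) * s / 1000.0).reshape(
            [-1 if i == ax else 1 for i in range(3)]
        )
        for ax, (n, s) in enumerate(zip(shape, spacing_um))
    ]


def _ellipsoid(coords, center_mm, semi_mm):
    z, y, x = coords
    return (
        ((z - center_mm[0]) / semi_mm[0]) ** 2
        + ((y - center_mm[1]) / semi_mm[1]) ** 2
        + ((x - center_mm[2]) / semi_mm[2]) ** 2
    ) <= 1.0


def _bbox(mask: np.ndarray) -> Box:
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise DataError("cannot take bounding box of an empty mask")
    return Box(tuple(int(i.min()) for i in idx), tuple(int(i.max()) + 1 for i in idx))


def _take_nearest(eligible_flat: np.ndarray, dist_flat: np.ndarray, n: int) -> np.ndarray:
    """Flat indices of the n eligible voxels with smallest distance."""
    cand = np.flatnonzero(eligible_flat)
    if cand.size < n:
        raise DataError(
            f"phantom geometry infeasible: need {n} voxels but only {cand.size} are eligible"
        )
    order = np.argpartition(dist_flat[cand], n - 1)[:n]
    return cand[order]


# ---------------------------------------------------------------------------
# generation


def _layout(spec: PhantomSpec):
    """Resolve body / pad / support geometry in mm; raise if it cannot fit."""
    Lz, Ly, Lx = spec.extent_mm
    dz, dy, dx = (s / 1000.0 for s in spec.voxel_spacing_um)

    if spec.body_axes_mm is not None:
        body_semi = tuple(float(v) for v in spec.body_axes_mm)
        if any(v <= 0 for v in body_semi):
            raise DataError("body semi-axes must be positive")
    else:
        body_semi = (0.45 * Lz, 0.26 * Ly, 0.42 * Lx)
    body_center = (0.5 * Lz, 0.36 * Ly, 0.5 * Lx)

    # fat pad: ellipsoid with (z, y, x) aspect (1.8, 1, 1.8)
    if spec.fat_pad_mass_g is not None:
        pad_vol = 1000.0 * spec.fat_pad_mass_g / spec.fat_density.value_g_per_ml
        pad_sy = (3.0 * pad_vol / (4.0 * np.pi * 1.8 * 1.8)) ** (1.0 / 3.0)
    else:
        pad_sy = 0.07 * Ly
    pad_semi = (1.8 * pad_sy, pad_sy, 1.8 * pad_sy)

    body_ymax = body_center[1] + body_semi[1]
    # air gap (2 vox) + support margin (5 vox) between body and pad surface
    pad_cy = body_ymax + 7.0 * dy + pad_semi[1]
    pad_center = (0.5 * Lz, pad_cy, 0.5 * Lx)

    bed_margin_vox = 5
    if pad_cy + pad_semi[1] + bed_margin_vox * dy > Ly:
        raise DataError(
            "phantom geometry infeasible: fat pad and its support do not fit "
            f"dorsally to the body (grid y extent {Ly:.1f} mm)"
        )
    for ax, (c, s, L) in enumerate(zip(body_center, body_semi, (Lz, Ly, Lx))):
        if c - s < 0 or c + s > L:
            raise DataError(f"phantom geometry infeasible: body exceeds grid on axis {_ax(ax)}")
    if pad_center[0] + pad_semi[0] > Lz or pad_center[2] + pad_semi[2] > Lx:
        raise DataError("phantom geometry infeasible: fat pad exceeds grid in z or x")

    body_vol_analytic = 4.0 / 3.0 * np.pi * float(np.prod(body_semi))
    lung_total = spec.lung_volume_mm3 if spec.lung_volume_mm3 is not None else 0.018 * body_vol_analytic
    # two prolate (2, 1, 1) lungs
    lung_r = (3.0 * (lung_total / 2.0) / (4.0 * np.pi * 2.0)) ** (1.0 / 3.0)
    lung_semi = (2.0 * lung_r, lung_r, lung_r)
    lung_centers = [
        (body_center[0] + 0.45 * body_semi[0], body_center[1] - 0.05 * body_semi[1],
         body_center[2] + sgn * 0.38 * body_semi[2])
        for sgn in (+1, -1)
    ]
    # exact lung containment is checked after voxelisation in generate_phantom
    return body_center, body_semi, pad_center, pad_semi, lung_centers, lung_semi, bed_margin_vox


def _ax(i: int) -> str:
    return ("z", "y", "x")[i]


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one seeded phantom: HU volume, label volume and ground truth.

    Deterministic in ``spec.seed`` (bit-identical volumes for identical spec
    and seed). The realized body fat-voxel fraction matches
    ``spec.fat_fraction_target`` to well within 2 percentage points because
    depot voxels are selected by exact count.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    coords = _coord_grids_mm(shape, spec.voxel_spacing_um)
    (body_center, body_semi, pad_center, pad_semi,
     lung_centers, lung_semi, bed_margin) = _layout(spec)

    body = _ellipsoid(coords, body_center, body_semi)
    n_body = int(body.sum())
    if n_body == 0:
        raise DataError("phantom geometry infeasible: body contains no voxels")

    labels = np.zeros(shape, dtype=np.uint8)  # AIR
    labels[body] = SOFT

    # fat pad + support block (bed) dorsal to the animal
    pad = _ellipsoid(coords, pad_center, pad_semi)
    if not pad.any():
        raise DataError("phantom geometry infeasible: fat pad contains no voxels")
    pad_bbox = _bbox(pad)
    bed_box = pad_bbox.dilate(bed_margin, shape)
    bed = np.zeros(shape, dtype=bool)
    bed[bed_box.slices] = True
    if (bed & ndimage.binary_dilation(body, iterations=2)).any():
        raise DataError("phantom geometry infeasible: fat-pad support touches the body")
    labels[bed] = BED
    labels[pad] = FAT_PAD

    # lungs
    lung = np.zeros(shape, dtype=bool)
    for lc in lung_centers:
        lung |= _ellipsoid(coords, lc, lung_semi)
    if not lung.any():
        raise DataError("phantom geometry infeasible: lungs contain no voxels")
    if (lung & ~body).any():
        raise DataError("phantom geometry infeasible: lungs extend outside the body")
    labels[lung] = LUNG

    z, y, x = coords
    flat = labels.ravel()

    # bone: dorsal spine rod, exact voxel count nearest to the spine axis
    n_bone = int(round(spec.bone_fraction * n_body))
    if n_bone > 0:
        spine_y = body_center[1] + 0.5 * body_semi[1]
        spine_x = body_center[2]
        d_spine = ((y - spine_y) ** 2 + (x - spine_x) ** 2) + 0.0 * z
        lung_guard = ndimage.binary_dilation(lung, iterations=2)
        eligible = body & ~lung_guard
        idx = _take_nearest(eligible.ravel(), d_spine.ravel(), n_bone)
        flat[idx] = BONE
    bone = labels == BONE

    # fat depots: exact counts, buried under >=0.3 mm of soft tissue
    n_fat = int(round(spec.fat_fraction_target * n_body))
    n_visc = int(round((1.0 - spec.sc_fat_share) * n_fat))
    n_sc = n_fat - n_visc
    depth = ndimage.distance_transform_edt(body, sampling=[s / 1000.0 for s in spec.voxel_spacing_um])
    guard = ndimage.binary_dilation(lung | bone, iterations=2)
    eligible = body & (depth >= spec.depot_burial_mm) & ~guard

    def depot_distance(centers, z_stretch=1.6):
        d = None
        for c in centers:
            dc = ((z - c[0]) / z_stretch) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2
            d = dc if d is None else np.minimum(d, dc)
        return d

    cz, cy, cx = body_center
    bz, by, bx = body_semi
    visc_centers = [(cz - 0.35 * bz, cy - 0.05 * by, cx + 0.28 * bx),
                    (cz - 0.35 * bz, cy - 0.10 * by, cx - 0.28 * bx)]
    sc_centers = [(cz - 0.38 * bz, cy + 0.42 * by, cx + 0.55 * bx),
                  (cz - 0.38 * bz, cy + 0.42 * by, cx - 0.55 * bx),
                  (cz + 0.05 * bz, cy - 0.45 * by, cx + 0.50 * bx),
                  (cz + 0.05 * bz, cy - 0.45 * by, cx - 0.50 * bx)]

    elig_flat = eligible.ravel().copy()
    if n_visc > 0:
        idx_v = _take_nearest(elig_flat, depot_distance(visc_centers).ravel(), n_visc)
        flat[idx_v] = FAT_VISC
        elig_flat[idx_v] = False
    if n_sc > 0:
        idx_s = _take_nearest(elig_flat, depot_distance(sc_centers).ravel(), n_sc)
        flat[idx_s] = FAT_SC

    # ideal HU field -> PSF blur -> motion blur -> noise -> CT clamp
    hu = spec.tissue.lookup()[labels]
    if spec.psf_sigma_vox > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.psf_sigma_vox, mode="reflect")
    if spec.motion_sigma_vox > 0:
        hu = ndimage.gaussian_filter1d(hu, sigma=spec.motion_sigma_vox, axis=0, mode="reflect")
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        unit = rng.standard_normal(shape, dtype=np.float32)
        hu = hu + np.float32(spec.noise_sd_hu) * unit
    hu = np.clip(hu, -1024.0, 3072.0).astype(np.float32)

    volume = VoxelVolume(hu, spec.voxel_spacing_um)
    label_volume = LabelVolume(labels, spec.voxel_spacing_um)
    truth = _ground_truth(spec, labels, pad_bbox, bed_box)

    realized = truth.true_fat_fraction
    if abs(realized - spec.fat_fraction_target) > 0.02:
        raise DataError(
            f"realized fat fraction {realized:.3f} deviates from target "
            f"{spec.fat_fraction_target:.3f} by more than 2 percentage points"
        )
    return Phantom(volume, label_volume, truth)


def _ground_truth(spec: PhantomSpec, labels: np.ndarray, pad_bbox: Box, bed_box: Box) -> GroundTruth:
    v = spec.voxel_volume_mm3
    counts = np.bincount(labels.ravel(), minlength=len(LABEL_NAMES))
    voxel_counts = {LABEL_NAMES[c]: int(counts[c]) for c in LABEL_NAMES}
    volumes = {name: n * v for name, n in voxel_counts.items()}
    n_body = sum(counts[c] for c in BODY_LABELS)
    fat_fraction = (counts[FAT_SC] + counts[FAT_VISC]) / n_body
    pad_volume = counts[FAT_PAD] * v
    pad_mass = pad_volume * spec.fat_density.value_g_per_ml / 1000.0
    lung_roi = _bbox(labels == LUNG).dilate(2, labels.shape)
    return GroundTruth(
        voxel_counts=voxel_counts,
        volumes_mm3=volumes,
        true_fat_fraction=float(fat_fraction),
        fat_pad_volume_mm3=float(pad_volume),
        fat_pad_mass_g=float(pad_mass),
        voxel_volume_mm3=v,
        pad_roi=pad_bbox.dilate(2, labels.shape),
        lung_roi=lung_roi,
        bed_box=bed_box,
    )


def fat_pad_spec(truth: GroundTruth, density: FatDensity | None = None):
    """Build the calibration reference from a phantom's ground truth.

    The pad mass is derived from the realized voxel volume and the fat
    density, so the density-derived target volume equals the true pad volume
    exactly — the loop the physical experiment closes with a scale.
    """
    from .segmentation import FatPadSpec  # local import to avoid a cycle

    density = density or DEFAULT_FAT_DENSITY
    mass_g = truth.fat_pad_volume_mm3 * density.value_g_per_ml / 1000.0
    return FatPadSpec(mass_g=mass_g, density=density, roi=truth.pad_roi)


# ---------------------------------------------------------------------------
# acquisition-style transforms


def apply_motion_blur(vol: VoxelVolume, sigma_vox: float) -> VoxelVolume:
    """Emulate an ungated acquisition: 1-D Gaussian blur along cranio-caudal z."""
    if sigma_vox < 0:
        raise DataError(f"motion sigma must be non-negative, got {sigma_vox}")
    if sigma_vox == 0:
        return vol.with_data(vol.data.copy())
    blurred = ndimage.gaussian_filter1d(
        vol.data.astype(np.float32, copy=False), sigma=sigma_vox, axis=0, mode="reflect"
    )
    return vol.with_data(blurred)


def split_fields_of_view(vol: VoxelVolume, n_fov: int, overlap_vox: int) -> list[VoxelVolume]:
    """Split a whole-body volume into overlapping axial fields of view.

    Blocks are contiguous along z, cover the whole volume, and consecutive
    blocks share exactly ``overlap_vox`` slices. Each block carries its
    physical offset in ``origin_mm`` so :func:`adipoct.segmentation.stitch`
    can reassemble the whole-body volume.
    """
    nz = vol.shape[0]
    if n_fov < 2:
        raise DataError(f"n_fov must be >= 2, got {n_fov}")
    if overlap_vox < 0:
        raise DataError("overlap must be non-negative")
    block = int(np.ceil((nz + (n_fov - 1) * overlap_vox) / n_fov))
    if block - overlap_vox <= 0 or block > nz:
        raise DataError(
            f"overlap {overlap_vox} does not fit {n_fov} fields of view on a {nz}-slice axis"
        )
    dz_mm = vol.spacing_um[0] / 1000.0
    fovs = []
    for i in range(n_fov):
        start = i * (block - overlap_vox)
        stop = nz if i == n_fov - 1 else min(start + block, nz)
        origin = (vol.origin_mm[0] + start * dz_mm, vol.origin_mm[1], vol.origin_mm[2])
        fovs.append(VoxelVolume(vol.data[start:stop].copy(), vol.spacing_um, origin))
    return fovs
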