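"""Body-composition quantities derived from segmentation volumes.

The scan-level summary is the triple (total, fat, lean) volume in cm^3 and
the ratios fat/total and lean/total; the fat ratio is the scan's fat-mass
fraction FM (%). Combining the fraction with the animal's body mass gives a
theoretical fat mass in grams that can be compared against harvested
adipose tissue at autopsy, which is how threshold-based CT and bioimpedance
estimates are benchmarked against the scale.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult
from .volume_io import DataError

LEAN_RANGE_DEFAULT = (-150.0, 300.0)
_FRACTION_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class BodyComposition:
    """Total/fat/lean volumes (cm^3) and the fat/total, lean/total ratios."""

    total_volume_cm3: float
    fat_volume_cm3: float
    lean_volume_cm3: float
    fat_fraction: float
    lean_fraction: float

    def __post_init__(self):
        if self.total_volume_cm3 <= 0:
            raise DataError("total volume must be positive")
        if self.fat_volume_cm3 > self.total_volume_cm3 * (1 + _FRACTION_TOL):
            raise DataError("fat volume exceeds total volume")
        if self.lean_volume_cm3 > self.total_volume_cm3 * (1 + _FRACTION_TOL):
            raise DataError("lean volume exceeds total volume")
        if self.fat_fraction + self.lean_fraction > 1.0 + 1e-6:
            raise DataError(
                "fat and lean fractions overlap: bands may abut but never share voxels"
            )

    @classmethod
    def from_volumes_cm3(cls, total: float, fat: float, lean: float) -> "BodyComposition":
        if total <= 0:
            raise DataError("total volume must be positive")
        return cls(
            total_volume_cm3=float(total),
            fat_volume_cm3=float(fat),
            lean_volume_cm3=float(lean),
            fat_fraction=float(fat) / float(total),
            lean_fraction=float(lean) / float(total),
        )

    def report_row(self, ndigits: int = 2) -> dict:
        """Two-decimal report row matching the conventional table layout."""
        return {
            "total_cm3": round(self.total_volume_cm3, ndigits),
            "fat_cm3": round(self.fat_volume_cm3, ndigits),
            "lean_cm3": round(self.lean_volume_cm3, ndigits),
            "fat_fraction": round(self.fat_fraction, ndigits),
            "lean_fraction": round(self.lean_fraction, ndigits),
        }


def compute_composition(
    body: SegmentationResult,
    fat: SegmentationResult,
    lean: SegmentationResult,
) -> BodyComposition:
    """Composition from whole-body, fat and lean segmentations (mm^3 -> cm^3)."""
    if not (fat.mask.data & ~body.mask.data).sum() == 0:
        raise DataError("fat mask is not a subset of the body mask")
    if not (lean.mask.data & ~body.mask.data).sum() == 0:
        raise DataError("lean mask is not a subset of the body mask")
    if (fat.mask.data & lean.mask.data).any():
        raise DataError("fat and lean masks overlap; bands must not share voxels")
    return BodyComposition.from_volumes_cm3(
        total=body.volume_mm3 / 1000.0,
        fat=fat.volume_mm3 / 1000.0,
        lean=lean.volume_mm3 / 1000.0,
    )


def theoretical_fat_mass(body_mass_g: float, fat_fraction: float) -> float:
    """Fat mass (g) implied by body mass and an imaging fat fraction."""
    if body_mass_g <= 0:
        raise DataError(f"body mass must be positive, got {body_mass_g} g")
    if not (0.0 <= fat_fraction <= 1.0):
        raise DataError(f"fat fraction must lie in [0, 1], got {fat_fraction}")
    return body_mass_g * fat_fraction


@dataclasses.dataclass(frozen=True)
class AnimalRecord:
    """Per-animal inputs for the method-agreement analysis."""

    animal_id: str
    body_mass_g: float
    harvested_fat_g: float | None = None
    fm_bis_fraction: float | None = None
    fm_uct_fraction: float | None = None

    def __post_init__(self):
        if self.body_mass_g <= 0:
            raise DataError("body mass must be positive")
        for name in ("fm_bis_fraction", "fm_uct_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must lie in [0, 1], got {v}")
        if self.harvested_fat_g is not None and self.harvested_fat_g < 0:
            raise DataError("harvested fat mass cannot be negative")


_METHOD_COLUMNS = {"BIS": "fm_bis_fraction", "uCT": "fm_uct_fraction"}


def records_to_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def overestimation_summary(records: Sequence[AnimalRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-method bias of theoretical fat mass against harvested fat.

    For each method with available fractions, reports the mean of the
    per-animal differences (theoretical - harvested, in g) and the slope of
    those differences regressed on harvested fat mass; a negative slope
    means the overestimation is concentrated in the leanest animals.
    """
    from .stats import linfit

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if "harvested_fat_g" not in df or df["harvested_fat_g"].isna().all():
        raise DataError("harvested fat masses are required for the bias analysis")
    rows = []
    for method, col in _METHOD_COLUMNS.items():
        if col not in df:
            continue
        sub = df.dropna(subset=["harvested_fat_g", col])
        if len(sub) == 0:
            continue
        theoretical = sub["body_mass_g"].to_numpy() * sub[col].to_numpy()
        harvested = sub["harvested_fat_g"].to_numpy(dtype=float)
        bias = theoretical - harvested
        if len(sub) >= 3 and np.ptp(harvested) > 0 and np.ptp(bias) > 0:
            slope = linfit(harvested, bias).slope
        elif len(sub) >= 2 and np.ptp(harvested) > 0:
            slope = float(np.polyfit(harvested, bias, 1)[0])
        else:
            slope = float("nan")
        rows.append(
            {
                "method": method,
                "n": int(len(sub)),
                "mean_bias_g": float(bias.mean()),
                "sd_bias_g": float(bias.std(ddof=1)) if len(sub) > 1 else 0.0,
                "bias_vs_harvested_slope": slope,
            }
        )
    if not rows:
        raise DataError("no method has both harvested fat and an imaging fat fraction")
    return pd.DataFrame(rows)
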