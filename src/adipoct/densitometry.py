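"""Fat density from replicate mass/volume measurements, and mass <-> volume.

The reference workflow weighs an excised fat sample and reads the displaced
volume off a graduated tube (0.05 mL resolution); density is the mean of the
per-replicate ``mass / volume`` ratios. The resulting constant (0.92 g/mL
for murine adipose tissue) converts the calibration fat pad's mass into the
target volume the threshold search must reproduce.

Units: densities are handled in g/mL (== g/cm^3). Source tables sometimes
print adipose density as "mg/mL"; that reading is dimensionally inconsistent
with fat (~0.92 g/cm^3), so values are interpreted as g/mL and the
interpretation is logged rather than silently applied.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEPOTS = ("visceral", "subcutaneous")
_DEPOT_ALIASES = {"visceral": "visceral", "abdominal": "visceral", "subcutaneous": "subcutaneous"}


@dataclasses.dataclass(frozen=True)
class DensityMeasurement:
    """One replicate: sample mass (g) and displaced volume (mL) for a depot."""

    mass_g: float
    volume_ml: float
    depot: str

    def __post_init__(self):
        if self.mass_g <= 0:
            raise ValueError(f"mass must be positive, got {self.mass_g} g")
        if self.volume_ml <= 0:
            raise ValueError(f"volume must be positive, got {self.volume_ml} mL")
        depot = _DEPOT_ALIASES.get(str(self.depot).lower())
        if depot is None:
            raise ValueError(f"unknown depot {self.depot!r}; expected one of {sorted(_DEPOT_ALIASES)}")
        object.__setattr__(self, "depot", depot)

    @property
    def density_g_per_ml(self) -> float:
        return self.mass_g / self.volume_ml


@dataclasses.dataclass(frozen=True)
class FatDensity:
    """Adipose density in g/mL with its replicate spread."""

    value_g_per_ml: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self):
        if not (0.5 < self.value_g_per_ml < 1.5):
            raise ValueError(
                f"fat density {self.value_g_per_ml} g/mL is outside the plausible "
                "adipose band (0.5, 1.5)"
            )
        if self.sd < 0:
            raise ValueError("density SD must be non-negative")


#: literature-consistent default measured with the displacement protocol
DEFAULT_FAT_DENSITY = FatDensity(value_g_per_ml=0.92, sd=0.01, n=10)


def compute_density(measurements: Sequence[DensityMeasurement]) -> FatDensity:
    """Mean and sample SD of per-replicate densities d = m / v."""
    if len(measurements) == 0:
        raise ValueError("at least one density measurement is required")
    d = np.array([m.density_g_per_ml for m in measurements], dtype=float)
    logger.info("fat density unit interpreted as g/mL (g/cm^3)")
    # identical replicates have exactly zero spread (no rounding residue)
    sd = float(d.std(ddof=1)) if d.size > 1 and np.ptp(d) > 0 else 0.0
    return FatDensity(value_g_per_ml=float(d.mean()), sd=sd, n=int(d.size))


def mass_to_volume(mass_g: float, density: FatDensity | float) -> float:
    """Convert a fat mass (g) to a volume in mm^3 (1 mL = 1000 mm^3)."""
    if mass_g <= 0:
        raise ValueError(f"mass must be positive, got {mass_g} g")
    value = density.value_g_per_ml if isinstance(density, FatDensity) else float(density)
    if value <= 0:
        raise ValueError("density must be positive")
    return 1000.0 * mass_g / value


@dataclasses.dataclass(frozen=True)
class DepotComparison:
    visceral_mean: float
    visceral_sd: float
    subcutaneous_mean: float
    subcutaneous_sd: float

    @property
    def difference(self) -> float:
        """visceral minus subcutaneous mean density (g/mL)."""
        return self.visceral_mean - self.subcutaneous_mean


def compare_depot_densities(measurements: Sequence[DensityMeasurement]) -> DepotComparison:
    """Per-depot mean +/- SD and the visceral - subcutaneous difference."""
    by_depot = {d: [m.density_g_per_ml for m in measurements if m.depot == d] for d in DEPOTS}
    for depot, values in by_depot.items():
        if not values:
            raise ValueError(f"no measurements for depot {depot!r}")
    stats = {}
    for depot, values in by_depot.items():
        arr = np.asarray(values, dtype=float)
        stats[depot] = (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
    return DepotComparison(
        visceral_mean=stats["visceral"][0],
        visceral_sd=stats["visceral"][1],
        subcutaneous_mean=stats["subcutaneous"][0],
        subcutaneous_sd=stats["subcutaneous"][1],
    )


def read_measurements_csv(path: str | Path) -> list[DensityMeasurement]:
    """Read replicate measurements from a CSV with columns depot, mass_g, volume_ml."""
    path = Path(path)
    out = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"depot", "mass_g", "volume_ml"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path.name} must have columns {sorted(required)}")
        for row in reader:
            out.append(
                DensityMeasurement(
                    mass_g=float(row["mass_g"]),
                    volume_ml=float(row["volume_ml"]),
                    depot=row["depot"],
                )
            )
    if not out:
        raise ValueError(f"{path.name} contains no measurements")
    return out


def simulate_density_measurements(
    n_samples_per_depot: int = 5,
    n_replicates: int = 5,
    true_density: float = 0.92,
    reading_sd_ml: float = 0.02,
    tube_resolution_ml: float = 0.05,
    seed: int = 0,
) -> list[DensityMeasurement]:
    """Emulate the displacement protocol: repeated tube readings of one sample.

    Each sample has a fixed true mass; every replicate volume reading carries
    Gaussian reading error and is quantised to the graduated-tube resolution.
    """
    rng = np.random.default_rng(seed)
    out = []
    for depot in DEPOTS:
        for _ in range(n_samples_per_depot):
            mass = float(rng.uniform(0.9, 2.2))
            true_volume = mass / true_density
            for _ in range(n_replicates):
                reading = true_volume + rng.normal(0.0, reading_sd_ml)
                reading = max(round(reading / tube_resolution_ml) * tube_resolution_ml,
                              tube_resolution_ml)
                out.append(DensityMeasurement(mass_g=mass, volume_ml=reading, depot=depot))
    return out
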