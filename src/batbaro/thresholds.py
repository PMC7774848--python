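"""Mammalian pressure-mortality thresholds and safety ratios.

No decompression data exist for bats; the comparison therefore uses the
published rodent data: rapid-decompression outcomes in rats (and one rabbit
series) for the low-pressure side, and blast-overpressure LD50 levels (the
mouse value, 184 kPa at 20.7 g body mass, is closest to bat body mass) for
the high-pressure side.  The low-pressure mortality threshold is the
smallest pressure-drop magnitude at which any mortality was observed
(58.6 kPa below atmospheric in rats); predicted turbine exposures are
reported as the factor by which they fall short of these thresholds.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DecompressionRecord",
    "BlastRecord",
    "load_decompression_records",
    "load_blast_records",
    "mortality_threshold_low",
    "safety_ratio",
    "build_report",
    "fit_blast_allometry",
]


@dataclass(frozen=True)
class DecompressionRecord:
    """One rapid-decompression exposure series."""

    species: str
    body_mass_g: float
    delta_p_pa: float  # negative = below ambient
    duration_s: float
    hemorrhage_pct: float
    mortality_pct: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        for name in ("hemorrhage_pct", "mortality_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class BlastRecord:
    """One blast-overpressure LD50 entry."""

    species: str
    body_mass_g: float
    ld50_overpressure_pa: float

    def __post_init__(self) -> None:
        if self.ld50_overpressure_pa <= 0:
            raise ValueError("LD50 overpressure must be positive")


def load_decompression_records(path: str | Path) -> tuple[DecompressionRecord, ...]:
    """Read a decompression table: columns species, mass_g, delta_p_Pa,
    duration_s, hemorrhage_pct, mortality_pct."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return tuple(
            DecompressionRecord(
                species=row["species"],
                body_mass_g=float(row["mass_g"]),
                delta_p_pa=float(row["delta_p_Pa"]),
                duration_s=float(row["duration_s"]),
                hemorrhage_pct=float(row["hemorrhage_pct"]),
                mortality_pct=float(row["mortality_pct"]),
            )
            for row in reader
        )


def load_blast_records(path: str | Path) -> tuple[BlastRecord, ...]:
    """Read a blast LD50 table: columns species, mass_g, ld50_Pa."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return tuple(
            BlastRecord(
                species=row["species"],
                body_mass_g=float(row["mass_g"]),
                ld50_overpressure_pa=float(row["ld50_Pa"]),
            )
            for row in reader
        )


def mortality_threshold_low(records: Sequence[DecompressionRecord]) -> float:
    """Smallest pressure-drop magnitude (Pa) with any observed mortality."""
    fatal = [abs(r.delta_p_pa) for r in records if r.mortality_pct > 0]
    if not fatal:
        raise ValueError("no record in the table shows mortality")
    return min(fatal)


def safety_ratio(threshold: float, predicted: float) -> tuple[float, int]:
    """How many times smaller the predicted exposure is than the threshold.

    Returns ``(ratio, rounded)`` where ``ratio = |threshold| / |predicted|``
    and ``rounded`` uses round-half-away-from-zero, matching the convention
    of the printed comparisons.
    """
    if predicted == 0:
        raise ValueError("predicted exposure must be non-zero")
    ratio = abs(threshold) / abs(predicted)
    rounded = int(math.floor(ratio + 0.5))
    return ratio, rounded


def build_report(
    summary: "pd.DataFrame",
    decompression: Sequence[DecompressionRecord],
    blast: Sequence[BlastRecord],
) -> dict:
    """Per-wind-speed comparison of predicted exposures with the thresholds.

    ``summary`` is the exposure-summary table (columns ``u_inf_mps``,
    ``dp_min_path_1mm_Pa``, ``dp_min_vortex_Pa``, ``dp_max_path_1mm_Pa``).
    For each wind speed and mechanism the report carries the predicted
    pressure change, the applicable threshold, and the safety ratio.
    """
    if len(summary) == 0:
        raise ValueError("empty exposure summary")
    required = {"u_inf_mps", "dp_min_path_1mm_Pa", "dp_min_vortex_Pa", "dp_max_path_1mm_Pa"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary table is missing columns {sorted(missing)}")

    low_threshold = mortality_threshold_low(decompression)
    mouse_like = min(blast, key=lambda r: r.body_mass_g)

    mechanisms = {
        "blade_low": ("dp_min_path_1mm_Pa", low_threshold, "rodent_low_pressure_mortality"),
        "vortex_low": ("dp_min_vortex_Pa", low_threshold, "rodent_low_pressure_mortality"),
        "blade_high": (
            "dp_max_path_1mm_Pa",
            mouse_like.ld50_overpressure_pa,
            f"{mouse_like.species}_blast_ld50",
        ),
    }
    rows = []
    for _, row in summary.iterrows():
        for mech, (col, threshold, label) in mechanisms.items():
            predicted = float(row[col])
            ratio, rounded = safety_ratio(threshold, predicted)
            rows.append(
                {
                    "u_inf_mps": float(row["u_inf_mps"]),
                    "mechanism": mech,
                    "predicted_dp_Pa": predicted,
                    "threshold_Pa": float(threshold),
                    "threshold_label": label,
                    "safety_ratio": ratio,
                    "safety_ratio_rounded": rounded,
                }
            )
    return {
        "low_pressure_threshold_Pa": float(low_threshold),
        "high_pressure_ld50_Pa": float(mouse_like.ld50_overpressure_pa),
        "high_pressure_reference_species": mouse_like.species,
        "comparisons": rows,
    }


def fit_blast_allometry(records: Sequence[BlastRecord]) -> tuple[float, float]:
    """Optional log-log least-squares fit ``log10(LD50) = a + b log10(mass)``.

    Provided for exploring allometric scaling over user-supplied LD50 data;
    not anchored to any published regression.
    """
    if len(records) < 2:
        raise ValueError("need at least two records for a regression")
    x = np.log10([r.body_mass_g for r in records])
    y = np.log10([r.ld50_overpressure_pa for r in records])
    b, a = np.polyfit(x, y, 1)
    return float(a), float(b)
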