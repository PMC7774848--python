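"""Bundled and synthetic inputs: planform, polars, section shape, thresholds.

Everything the pipeline consumes is either vendored under
``batbaro/data`` (the transcribed public reference-turbine planform, the
parametric polar tables, the synthetic 64-series-like section, the threshold
tables) or generated here, so the whole analysis builds and tests offline.

``toy_rotor`` provides a uniform-chord rotor with an ideal analytic polar
(``Cl = 2 pi sin(alpha)``, ``Cd = 0``) for which the blade-element,
circulation and vortex stages have closed-form expectations — the rig for
the property tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .airfoil import AirfoilShape, read_airfoil_dat
from .bem import PolarTable, make_polar_table  # re-exported: regenerates the polar fixtures
from .geometry import BladePlanform, PlanformStation, load_planform
from .thresholds import (
    BlastRecord,
    DecompressionRecord,
    load_blast_records,
    load_decompression_records,
)

__all__ = [
    "FixtureSet",
    "data_path",
    "reference_fixture_set",
    "toy_rotor",
    "ideal_polar",
    "synthetic_threshold_tables",
    "AIRFOIL_POLAR_PARAMS",
]

#: Parametric polar model inputs per reference-blade airfoil family
#: (zero-lift angle deg, lift slope /rad, Cl_max, stall angle deg, Cd0),
#: fixed from the families' published aerodynamic characteristics.
AIRFOIL_POLAR_PARAMS: dict[str, dict] = {
    "cylinder1": {"drag_only": True, "cd0": 0.50},
    "cylinder2": {"drag_only": True, "cd0": 0.35},
    "du40_a17": {"alpha0_deg": -2.2, "cl_slope_per_rad": 6.0, "cl_max": 1.50, "stall_deg": 16.0, "cd0": 0.030},
    "du35_a17": {"alpha0_deg": -2.7, "cl_slope_per_rad": 6.1, "cl_max": 1.55, "stall_deg": 15.0, "cd0": 0.017},
    "du30_a17": {"alpha0_deg": -3.1, "cl_slope_per_rad": 6.2, "cl_max": 1.50, "stall_deg": 14.0, "cd0": 0.011},
    "du25_a17": {"alpha0_deg": -3.4, "cl_slope_per_rad": 6.2, "cl_max": 1.48, "stall_deg": 13.5, "cd0": 0.009},
    "du21_a17": {"alpha0_deg": -3.8, "cl_slope_per_rad": 6.2, "cl_max": 1.45, "stall_deg": 13.0, "cd0": 0.008},
    "naca64_a17": {"alpha0_deg": -4.2, "cl_slope_per_rad": 6.1, "cl_max": 1.45, "stall_deg": 12.5, "cd0": 0.007},
}


@dataclass(frozen=True)
class FixtureSet:
    """A mutually consistent bundle of pipeline inputs."""

    planform: BladePlanform
    polars: dict[str, PolarTable]
    section_shape: AirfoilShape
    decompression: tuple[DecompressionRecord, ...]
    blast: tuple[BlastRecord, ...]


def data_path(name: str) -> Path:
    """Path of a bundled data file."""
    return Path(str(resources.files("batbaro").joinpath("data", name)))


def reference_fixture_set() -> FixtureSet:
    """The 5-MW reference-turbine fixture bundle.

    17-station planform (63 m rotor radius, 3 blades), polar tables for each
    airfoil family, the synthetic 17%-thick 64-series-like section at 90%
    span, and the rodent decompression / blast-LD50 threshold tables.
    """
    planform = load_planform(data_path("nrel5mw_planform.csv"))
    polars = {
        aid: PolarTable.from_file(data_path(f"polar_{aid}_synthetic.csv"), airfoil_id=aid)
        for aid in AIRFOIL_POLAR_PARAMS
    }
    shape = read_airfoil_dat(data_path("naca64ish_17pct_synthetic.dat"))
    decompression = load_decompression_records(data_path("rodent_decompression_synthetic.csv"))
    blast = load_blast_records(data_path("blast_ld50.csv"))
    return FixtureSet(
        planform=planform,
        polars=polars,
        section_shape=shape,
        decompression=decompression,
        blast=blast,
    )


def ideal_polar(airfoil_id: str = "ideal") -> PolarTable:
    """Analytic lossless polar ``Cl = 2 pi sin(alpha)``, ``Cd = 0``."""
    alpha = np.arange(-180.0, 180.5, 0.5)
    cl = 2.0 * np.pi * np.sin(np.radians(alpha))
    return PolarTable(airfoil_id, alpha, cl, np.zeros_like(alpha))


def toy_rotor(
    n_stations: int = 9,
    chord: float = 1.0,
    twist: float = 0.0,
    rotor_radius: float = 10.0,
    zero_lift: bool = False,
) -> tuple[BladePlanform, dict[str, PolarTable]]:
    """Uniform-chord analytic rotor for property tests.

    Stations span 20%–97.5% of the rotor radius so the Prandtl loss factors
    stay regular; the polar is the ideal ``2 pi sin(alpha)`` curve (or a
    zero-lift curve when ``zero_lift``).
    """
    if n_stations < 2:
        raise ValueError("need at least 2 stations")
    if chord <= 0 or rotor_radius <= 0:
        raise ValueError("chord and rotor radius must be positive")
    radii = np.linspace(0.2 * rotor_radius, 0.975 * rotor_radius, n_stations)
    stations = tuple(
        PlanformStation(r_b=float(r), chord=chord, twist=twist, airfoil_id="ideal", thickness_ratio=0.12)
        for r in radii
    )
    planform = BladePlanform(
        stations=stations, rotor_radius=rotor_radius, hub_radius=0.0, n_blades=3
    )
    if zero_lift:
        alpha = np.arange(-180.0, 180.5, 1.0)
        polar = PolarTable("ideal", alpha, np.zeros_like(alpha), np.zeros_like(alpha))
    else:
        polar = ideal_polar()
    return planform, {"ideal": polar}


def synthetic_threshold_tables(
    seed: int,
    n_decompression: int = 12,
    n_blast: int = 4,
) -> tuple[tuple[DecompressionRecord, ...], tuple[BlastRecord, ...]]:
    """Randomized threshold tables honoring the printed constraints.

    Decompression exposures lie in [-86.5, -45.5] kPa with durations in
    [0.0021, 1.9] s; no mortality occurs below a 58 kPa drop and mortality
    begins exactly at 58.6 kPa.  Blast records are mouse-scale LD50 values
    anchored at the printed 184 kPa / 20.7 g point.  Reproducible for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    records: list[DecompressionRecord] = []
    # anchor records: the threshold onset and the range endpoints
    records.append(
        DecompressionRecord("rat", 168.0, -58600.0, float(rng.uniform(0.01, 0.5)), float(rng.uniform(40, 60)), float(rng.uniform(5, 20)))
    )
    records.append(DecompressionRecord("rat", 168.0, -45500.0, 1.9, float(rng.uniform(0, 20)), 0.0))
    records.append(DecompressionRecord("rat", 168.0, -86500.0, 0.0021, 100.0, float(rng.uniform(60, 100))))
    for _ in range(max(n_decompression - 3, 0)):
        mag = float(rng.uniform(45500.0, 86500.0))
        if 58000.0 < mag < 58600.0:
            mag = 57900.0  # keep the printed onset the smallest fatal magnitude
        duration = float(np.exp(rng.uniform(np.log(0.0021), np.log(1.9))))
        if mag < 58600.0:
            mortality = 0.0
        else:
            mortality = float(rng.uniform(5, 100))
        hemorrhage = float(min(100.0, rng.uniform(0, 40) + (mag - 45500.0) / 500.0))
        records.append(DecompressionRecord("rat", 168.0, -mag, duration, hemorrhage, mortality))
    blast = [BlastRecord("mouse", 20.7, 184000.0)]
    for i in range(max(n_blast - 1, 0)):
        mass = float(10 ** rng.uniform(2.0, 4.5))
        ld50 = float(184000.0 * (mass / 20.7) ** rng.uniform(0.1, 0.3))
        blast.append(BlastRecord(f"synthetic_mammal_{i+1}", mass, ld50))
    return tuple(records), tuple(blast)
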