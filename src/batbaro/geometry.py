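"""Reference-turbine geometry and operating schedule.

Holds the blade planform (ordered span stations with chord, twist and airfoil
identity), the scheduled operating points of the 5-MW reference machine at the
wind speeds where bats fly, and the section kinematics used by the
blade-element and pressure-field stages.

Conventions
-----------
* Span position ``r_b`` is measured from the rotation axis, in meters.
* Twist and pitch are in degrees, positive nose-into-the-wind.
* The rotor speed follows from the tip-speed ratio, ``omega = tsr * u_inf / R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "PlanformStation",
    "BladePlanform",
    "OperatingPoint",
    "PlanformError",
    "OperatingEnvelopeError",
    "CUT_IN_WIND_SPEED",
    "CUT_OUT_WIND_SPEED",
    "REFERENCE_SCHEDULE",
    "load_planform",
    "mean_chord",
    "section_at_fraction",
    "operating_point_for",
    "section_state_for",
    "section_kinematics",
]

#: Operating envelope of the reference turbine (m/s).
CUT_IN_WIND_SPEED = 3.0
CUT_OUT_WIND_SPEED = 25.0

#: Standard sea-level air properties (the study never varies them).
RHO_AIR = 1.225
P_ATM = 101325.0


class PlanformError(ValueError):
    """Raised for an invalid blade planform definition."""


class OperatingEnvelopeError(ValueError):
    """Raised when a wind speed falls outside the cut-in/cut-out envelope."""


@dataclass(frozen=True)
class PlanformStation:
    """One aerodynamic blade station."""

    r_b: float  # span position from rotation axis, m
    chord: float  # m
    twist: float  # deg
    airfoil_id: str
    thickness_ratio: float  # max thickness / chord

    def __post_init__(self) -> None:
        if self.chord <= 0:
            raise PlanformError(f"chord must be positive, got {self.chord}")
        if self.r_b <= 0:
            raise PlanformError(f"span position must be positive, got {self.r_b}")
        if not 0 < self.thickness_ratio < 1:
            raise PlanformError(
                f"thickness ratio must lie in (0, 1), got {self.thickness_ratio}"
            )


@dataclass(frozen=True)
class BladePlanform:
    """Ordered span stations of one blade plus rotor-level metadata."""

    stations: tuple[PlanformStation, ...]
    rotor_radius: float  # m
    hub_radius: float  # m
    n_blades: int

    def __post_init__(self) -> None:
        if len(self.stations) < 2:
            raise PlanformError("a planform needs at least 2 stations")
        radii = [s.r_b for s in self.stations]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise PlanformError("stations must be strictly increasing in span position")
        if radii[-1] > self.rotor_radius + 1e-9:
            raise PlanformError("outermost station lies beyond the rotor radius")
        if self.n_blades < 1:
            raise PlanformError("rotor needs at least one blade")


@dataclass(frozen=True)
class OperatingPoint:
    """One steady operating state of the turbine."""

    u_inf: float  # wind speed, m/s
    tsr: float  # tip-speed ratio
    pitch: float = 0.0  # collective blade pitch, deg
    rho: float = RHO_AIR  # kg/m^3
    p_inf: float = P_ATM  # Pa

    def __post_init__(self) -> None:
        if not CUT_IN_WIND_SPEED <= self.u_inf <= CUT_OUT_WIND_SPEED:
            raise OperatingEnvelopeError(
                f"wind speed {self.u_inf} m/s outside the "
                f"[{CUT_IN_WIND_SPEED}, {CUT_OUT_WIND_SPEED}] m/s envelope"
            )
        if self.tsr <= 0:
            raise OperatingEnvelopeError(f"tip-speed ratio must be positive, got {self.tsr}")

    def omega(self, rotor_radius: float) -> float:
        """Rotor angular speed (rad/s) for a rotor of the given radius."""
        return self.tsr * self.u_inf / rotor_radius


@dataclass(frozen=True)
class ScheduleRow:
    """Scheduled state at one wind speed, including the published 90%-span
    section state (relative wind speed and angle of attack) that drives the
    blade pressure-field stage."""

    u_inf: float
    pitch: float
    tsr: float
    u_rel_90: float  # m/s
    alpha_90: float  # deg


#: Operating schedule at the three study wind speeds.  The 90%-span relative
#: wind speed and angle of attack are the published aeroelastic values and are
#: treated as authoritative inputs to the pressure-field stage.
REFERENCE_SCHEDULE: tuple[ScheduleRow, ...] = (
    ScheduleRow(u_inf=5.0, pitch=0.0, tsr=10.0, u_rel_90=45.3, alpha_90=7.2),
    ScheduleRow(u_inf=7.5, pitch=0.0, tsr=7.7, u_rel_90=52.5, alpha_90=9.1),
    ScheduleRow(u_inf=10.0, pitch=0.0, tsr=7.6, u_rel_90=68.7, alpha_90=9.2),
)


def _parse_float(token: str, path: str, lineno: int, col: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise PlanformError(f"{path}:{lineno}: bad {col} value {token!r}") from exc


def load_planform(source: str | Path | Iterable[PlanformStation]) -> BladePlanform:
    """Load and validate a blade planform.

    ``source`` is either a delimited text file (columns ``r_b_m, chord_m,
    twist_deg, airfoil_id, thickness_ratio``; ``#``-prefixed metadata lines
    carry ``rotor_radius_m``, ``hub_radius_m`` and ``n_blades``) or an already
    built sequence of :class:`PlanformStation`, in which case rotor metadata
    defaults to the outermost station radius, zero hub and 3 blades.
    """
    if not isinstance(source, (str, Path)):
        stations = tuple(sorted(source, key=lambda s: s.r_b))
        radii = [s.r_b for s in stations]
        if len(set(radii)) != len(radii):
            raise PlanformError("duplicate span positions in station sequence")
        return BladePlanform(
            stations=stations,
            rotor_radius=stations[-1].r_b,
            hub_radius=0.0,
            n_blades=3,
        )

    path = Path(source)
    meta = {"rotor_radius_m": None, "hub_radius_m": 0.0, "n_blades": 3}
    stations: list[PlanformStation] = []
    header: list[str] | None = None
    required = ["r_b_m", "chord_m", "twist_deg", "airfoil_id", "thickness_ratio"]
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in meta:
                    meta[key] = float(val) if key != "n_blades" else int(float(val))
            continue
        fields = [f.strip() for f in line.replace("\t", ",").split(",") if f.strip()]
        if header is None:
            header = fields
            if header != required:
                raise PlanformError(
                    f"{path}:{lineno}: expected header {required}, got {header}"
                )
            continue
        if len(fields) != 5:
            raise PlanformError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        stations.append(
            PlanformStation(
                r_b=_parse_float(fields[0], str(path), lineno, "r_b_m"),
                chord=_parse_float(fields[1], str(path), lineno, "chord_m"),
                twist=_parse_float(fields[2], str(path), lineno, "twist_deg"),
                airfoil_id=fields[3],
                thickness_ratio=_parse_float(fields[4], str(path), lineno, "thickness_ratio"),
            )
        )
    if header is None:
        raise PlanformError(f"{path}: missing header row")
    radii = [s.r_b for s in stations]
    if len(set(radii)) != len(radii):
        raise PlanformError(f"{path}: duplicate span positions")
    rotor_radius = meta["rotor_radius_m"]
    if rotor_radius is None:
        rotor_radius = max(radii) if radii else 0.0
    return BladePlanform(
        stations=tuple(stations),
        rotor_radius=float(rotor_radius),
        hub_radius=float(meta["hub_radius_m"]),
        n_blades=int(meta["n_blades"]),
    )


def mean_chord(planform: BladePlanform) -> float:
    """Unweighted arithmetic mean of the station chords (m).

    This is the average chord entering the tip-vortex core-radius correlation
    ``r_c = 0.05 * mean_chord``.
    """
    return sum(s.chord for s in planform.stations) / len(planform.stations)


def section_at_fraction(planform: BladePlanform, f: float) -> PlanformStation:
    """Station nearest span fraction ``f`` of the rotor radius.

    The nearest-station rule (rather than interpolation) keeps the airfoil
    identity of the selected section unambiguous.
    """
    if not 0 < f <= 1:
        raise ValueError(f"span fraction must lie in (0, 1], got {f}")
    target = f * planform.rotor_radius
    return min(planform.stations, key=lambda s: abs(s.r_b - target))


def operating_point_for(u_inf: float, *, rho: float = RHO_AIR, p_inf: float = P_ATM) -> OperatingPoint:
    """Scheduled operating point at wind speed ``u_inf``.

    Returns the scheduled entry at 5, 7.5 and 10 m/s; the tip-speed ratio and
    pitch are interpolated linearly between scheduled speeds and held at the
    end values outside [5, 10] m/s (only the scheduled speeds are exercised by
    the study).  Wind speeds outside the cut-in/cut-out envelope are rejected.
    """
    if not CUT_IN_WIND_SPEED <= u_inf <= CUT_OUT_WIND_SPEED:
        raise OperatingEnvelopeError(
            f"wind speed {u_inf} m/s outside the "
            f"[{CUT_IN_WIND_SPEED}, {CUT_OUT_WIND_SPEED}] m/s envelope"
        )
    tsr = _interp_schedule(u_inf, "tsr")
    pitch = _interp_schedule(u_inf, "pitch")
    return OperatingPoint(u_inf=u_inf, tsr=tsr, pitch=pitch, rho=rho, p_inf=p_inf)


def section_state_for(u_inf: float) -> tuple[float, float]:
    """Published 90%-span section state ``(u_rel, alpha_deg)`` at ``u_inf``."""
    return _interp_schedule(u_inf, "u_rel_90"), _interp_schedule(u_inf, "alpha_90")


def _interp_schedule(u_inf: float, attr: str) -> float:
    rows = REFERENCE_SCHEDULE
    if u_inf <= rows[0].u_inf:
        return getattr(rows[0], attr)
    if u_inf >= rows[-1].u_inf:
        return getattr(rows[-1], attr)
    for lo, hi in zip(rows, rows[1:]):
        if lo.u_inf <= u_inf <= hi.u_inf:
            w = (u_inf - lo.u_inf) / (hi.u_inf - lo.u_inf)
            return (1 - w) * getattr(lo, attr) + w * getattr(hi, attr)
    raise AssertionError("unreachable")


def section_kinematics(
    op: OperatingPoint,
    f: float,
    a: float,
    a_tan: float,
    *,
    rotor_radius: float,
) -> tuple[float, float]:
    """Relative wind speed and inflow angle at span fraction ``f``.

    ``u_rel = sqrt((u_inf (1-a))^2 + (omega f R (1+a_tan))^2)`` with the
    inflow angle ``phi`` measured from the rotor plane, in degrees.  ``a`` and
    ``a_tan`` are the axial and tangential induction factors at the section.
    """
    if not 0 <= a < 1:
        raise ValueError(f"axial induction must lie in [0, 1), got {a}")
    axial = op.u_inf * (1.0 - a)
    tangential = op.omega(rotor_radius) * f * rotor_radius * (1.0 + a_tan)
    u_rel = math.hypot(axial, tangential)
    phi = math.degrees(math.atan2(axial, tangential))
    return u_rel, phi
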