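"""Blade-element momentum (BEM) solver and bound-circulation chain.

Computes spanwise induction, lift and bound circulation for the reference
rotor, then the blade-tip vortex strength as the maximum bound circulation
along the span (the classical potential-flow roll-up argument).  The solver is
a deterministic fixed-point iteration of the momentum / blade-element balance
with Prandtl tip and hub loss factors and the Buhl form of the Glauert
high-induction correction.

The Kutta–Joukowski relation ties lift per unit span to circulation,
``L' = rho * v * Gamma``, so ``Gamma = L'/(rho v) = 0.5 * c * Cl * v``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import BladePlanform, OperatingPoint, PlanformStation

__all__ = [
    "PolarTable",
    "SectionSolution",
    "SpanwiseCirculation",
    "BEMConvergenceError",
    "make_polar_table",
    "solve_bem_section",
    "circulation_from_lift",
    "spanwise_circulation",
    "tip_vortex_strength",
    "power_coefficient",
]

RELAXATION = 0.3
MAX_ITERATIONS = 500
RESIDUAL_TOL = 1e-8


class BEMConvergenceError(RuntimeError):
    """Raised when the induction fixed point fails to converge."""

    def __init__(self, message: str, residual_history: Sequence[float]):
        super().__init__(message)
        self.residual_history = list(residual_history)


@dataclass(frozen=True)
class PolarTable:
    """Tabulated lift/drag polar for one airfoil, over alpha in [-180, 180] deg."""

    airfoil_id: str
    alpha_deg: np.ndarray
    cl_values: np.ndarray
    cd_values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_deg, dtype=float)
        if a.ndim != 1 or a.size < 2 or np.any(np.diff(a) <= 0):
            raise ValueError("polar alphas must be a strictly increasing 1-D grid")
        if len(self.cl_values) != a.size or len(self.cd_values) != a.size:
            raise ValueError("polar column lengths differ")

    def cl(self, alpha_deg: float | np.ndarray) -> float | np.ndarray:
        return np.interp(alpha_deg, self.alpha_deg, self.cl_values)

    def cd(self, alpha_deg: float | np.ndarray) -> float | np.ndarray:
        return np.interp(alpha_deg, self.alpha_deg, self.cd_values)

    @classmethod
    def from_file(cls, path: str | Path, airfoil_id: str | None = None) -> "PolarTable":
        """Read a delimited polar file with header ``alpha_deg, cl, cd``."""
        path = Path(path)
        rows: list[tuple[float, float, float]] = []
        header_seen = False
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields != ["alpha_deg", "cl", "cd"]:
                    raise ValueError(f"{path}:{lineno}: expected header alpha_deg,cl,cd")
                header_seen = True
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            rows.append(tuple(float(f) for f in fields))  # type: ignore[arg-type]
        if not rows:
            raise ValueError(f"{path}: empty polar table")
        arr = np.array(rows)
        return cls(
            airfoil_id=airfoil_id or path.stem,
            alpha_deg=arr[:, 0],
            cl_values=arr[:, 1],
            cd_values=arr[:, 2],
        )

    def to_file(self, path: str | Path) -> None:
        lines = ["alpha_deg,cl,cd"]
        for a, cl, cd in zip(self.alpha_deg, self.cl_values, self.cd_values):
            lines.append(f"{a:.6g},{cl:.6g},{cd:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")


def make_polar_table(
    airfoil_id: str,
    *,
    alpha0_deg: float = 0.0,
    cl_slope_per_rad: float = 2.0 * math.pi,
    cl_max: float = 1.5,
    stall_deg: float = 14.0,
    cd0: float = 0.008,
    k_induced: float = 0.006,
    cd_max: float = 1.3,
    drag_only: bool = False,
) -> PolarTable:
    """Parametric polar: linear lift blended to a flat-plate curve post-stall.

    Attached flow follows ``Cl = slope * sin(alpha - alpha0)`` soft-limited at
    ``cl_max``; deep stall follows the flat-plate normal-force law
    ``Cn = cd_max * sin(alpha)`` with ``Cl = Cn cos(alpha)``,
    ``Cd = Cn sin(alpha)``; the two regimes are blended smoothly around the
    stall angle.  Attached drag is the parabolic ``cd0 + k * Cl^2``.
    ``drag_only`` produces a bluff (cylindrical) section: zero lift, constant
    drag ``cd0``.
    """
    coarse = np.arange(-180.0, 181.0, 5.0)
    fine = np.arange(-30.0, 30.01, 0.5)
    alpha = np.unique(np.round(np.concatenate([coarse, fine]), 6))
    if drag_only:
        cl = np.zeros_like(alpha)
        cd = np.full_like(alpha, cd0)
        return PolarTable(airfoil_id, alpha, cl, cd)

    a_rad = np.radians(alpha)
    a_eff = np.radians(alpha - alpha0_deg)
    # attached regime: genuinely linear (in sin) below stall, hard-capped at cl_max
    cl_att = np.clip(cl_slope_per_rad * np.sin(a_eff), -cl_max, cl_max)
    cd_att = cd0 + k_induced * cl_att**2

    cn_fp = cd_max * np.sin(a_rad)
    cl_fp = cn_fp * np.cos(a_rad)
    cd_fp = np.abs(cn_fp * np.sin(a_rad)) + cd0

    # cosine blend from fully attached at the stall angle to flat plate 15 deg
    # beyond it; the attached range itself is untouched
    past = np.clip((np.abs(alpha - alpha0_deg) - stall_deg) / 15.0, 0.0, 1.0)
    w = 0.5 * (1.0 + np.cos(np.pi * past))
    cl = w * cl_att + (1.0 - w) * cl_fp
    cd = w * cd_att + (1.0 - w) * cd_fp
    return PolarTable(airfoil_id, alpha, cl, cd)


@dataclass(frozen=True)
class SectionSolution:
    """Converged BEM state at one blade station."""

    station: PlanformStation
    a: float  # axial induction
    a_tan: float  # tangential induction
    phi: float  # inflow angle, deg
    alpha: float  # angle of attack, deg
    cl: float
    cd: float
    lift_per_span: float  # N/m
    v: float  # local relative air speed, m/s
    gamma: float  # bound circulation, m^2/s
    tip_loss: float  # combined Prandtl factor
    iterations: int
    residual: float


@dataclass(frozen=True)
class SpanwiseCirculation:
    """Bound circulation along the blade span."""

    points: tuple[tuple[float, float], ...]  # (r_b, gamma)
    solutions: tuple[SectionSolution, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("empty circulation distribution")

    @property
    def gamma_max(self) -> float:
        return max(g for _, g in self.points)

    @property
    def r_at_max(self) -> float:
        return max(self.points, key=lambda p: p[1])[0]


def circulation_from_lift(l_prime: float, rho: float, v: float) -> float:
    """Bound circulation from lift per unit span (Kutta–Joukowski)."""
    if v <= 0:
        raise ValueError(f"relative speed must be positive, got {v}")
    if rho <= 0:
        raise ValueError(f"density must be positive, got {rho}")
    return l_prime / (rho * v)


def _prandtl_factor(f: float) -> float:
    # guard the exp overflow for tiny sin(phi)
    if f > 50:
        return 1.0
    return (2.0 / math.pi) * math.acos(min(1.0, math.exp(-f)))


def solve_bem_section(
    planform: BladePlanform,
    op: OperatingPoint,
    station: PlanformStation,
    polar: PolarTable,
    *,
    relaxation: float = RELAXATION,
    max_iterations: int = MAX_ITERATIONS,
    tol: float = RESIDUAL_TOL,
) -> SectionSolution:
    """Converge the momentum / blade-element balance at one station.

    Fixed-point iteration on the induction factors ``(a, a')`` with
    under-relaxation; Prandtl tip and hub losses; Buhl's high-thrust
    correction replaces the momentum branch when the local thrust coefficient
    exceeds ``0.96 F``.
    """
    if op.u_inf <= 0:
        raise ValueError("wind speed must be positive for a BEM solution")
    if station not in planform.stations:
        raise ValueError("station does not belong to the given planform")
    r = station.r_b
    R = planform.rotor_radius
    B = planform.n_blades
    omega = op.omega(R)
    sigma = B * station.chord / (2.0 * math.pi * r)

    a, a_tan = 0.25, 0.0
    history: list[float] = []
    alpha = phi_deg = cl = cd = 0.0
    F = 1.0
    for iteration in range(1, max_iterations + 1):
        axial = op.u_inf * (1.0 - a)
        tangential = omega * r * (1.0 + a_tan)
        phi = math.atan2(axial, tangential)
        sphi = math.sin(phi)
        cphi = math.cos(phi)
        sphi_safe = math.copysign(max(abs(sphi), 1e-6), sphi if sphi != 0 else 1.0)

        f_tip = B * (R - r) / (2.0 * r * abs(sphi_safe))
        F_tip = _prandtl_factor(f_tip)
        if planform.hub_radius > 0 and r > planform.hub_radius:
            f_hub = B * (r - planform.hub_radius) / (2.0 * r * abs(sphi_safe))
            F_hub = _prandtl_factor(f_hub)
        else:
            F_hub = 1.0
        F = max(F_tip * F_hub, 1e-4)

        phi_deg = math.degrees(phi)
        alpha = phi_deg - station.twist - op.pitch
        cl = float(polar.cl(alpha))
        cd = float(polar.cd(alpha))
        cn = cl * cphi + cd * sphi
        ct = cl * sphi - cd * cphi

        ct_thrust = sigma * (1.0 - a) ** 2 * cn / (sphi_safe**2)
        if ct_thrust > 0.96 * F:
            # Buhl's empirical high-induction relation, inverted for a
            disc = ct_thrust * (50.0 - 36.0 * F) + 12.0 * F * (3.0 * F - 4.0)
            a_new = (18.0 * F - 20.0 - 3.0 * math.sqrt(max(disc, 0.0))) / (36.0 * F - 50.0)
        else:
            denom = 4.0 * F * sphi_safe**2 / max(sigma * cn, 1e-12)
            a_new = 1.0 / (denom + 1.0) if cn > 0 else 0.0
        a_new = min(max(a_new, 0.0), 0.999)

        denom_t = 4.0 * F * sphi_safe * cphi / (sigma * ct) - 1.0 if ct != 0 else math.inf
        a_tan_new = 1.0 / denom_t if math.isfinite(denom_t) and abs(denom_t) > 1e-9 else 0.0
        a_tan_new = min(max(a_tan_new, -0.5), 1.0)

        residual = max(abs(a_new - a), abs(a_tan_new - a_tan))
        history.append(residual)
        a += relaxation * (a_new - a)
        a_tan += relaxation * (a_tan_new - a_tan)
        if residual < tol:
            break
    else:
        raise BEMConvergenceError(
            f"BEM did not converge at r={r:.2f} m after {max_iterations} iterations "
            f"(last residual {history[-1]:.3e})",
            history,
        )

    v = math.hypot(op.u_inf * (1.0 - a), omega * r * (1.0 + a_tan))
    lift_per_span = 0.5 * op.rho * v**2 * station.chord * cl
    gamma = circulation_from_lift(lift_per_span, op.rho, v) if v > 0 else 0.0
    return SectionSolution(
        station=station,
        a=a,
        a_tan=a_tan,
        phi=phi_deg,
        alpha=alpha,
        cl=cl,
        cd=cd,
        lift_per_span=lift_per_span,
        v=v,
        gamma=gamma,
        tip_loss=F,
        iterations=iteration,
        residual=history[-1],
    )


def spanwise_circulation(
    planform: BladePlanform,
    op: OperatingPoint,
    polars: Mapping[str, PolarTable],
) -> SpanwiseCirculation:
    """Bound circulation ``Gamma(r_b)`` over all stations of the planform."""
    solutions = []
    for station in planform.stations:
        try:
            polar = polars[station.airfoil_id]
        except KeyError as exc:
            raise KeyError(f"no polar table for airfoil {station.airfoil_id!r}") from exc
        solutions.append(solve_bem_section(planform, op, station, polar))
    points = tuple((s.station.r_b, s.gamma) for s in solutions)
    return SpanwiseCirculation(points=points, solutions=tuple(solutions))


def tip_vortex_strength(dist: SpanwiseCirculation) -> float:
    """Tip-vortex strength: the maximum bound circulation along the span.

    Potential-flow roll-up assumption — the shed vorticity outboard of the
    circulation maximum rolls up into a single tip vortex of that strength.
    """
    return dist.gamma_max


def power_coefficient(
    planform: BladePlanform,
    op: OperatingPoint,
    polars: Mapping[str, PolarTable],
) -> float:
    """Rotor power coefficient from the converged spanwise BEM solution.

    Integrates the blade-element torque over the tabulated stations with the
    trapezoid rule; used to check the solution against the Betz limit.
    """
    dist = spanwise_circulation(planform, op, polars)
    r = np.array([s.station.r_b for s in dist.solutions])
    dq = np.array(
        [
            planform.n_blades
            * 0.5
            * op.rho
            * s.v**2
            * s.station.chord
            * (s.cl * math.sin(math.radians(s.phi)) - s.cd * math.cos(math.radians(s.phi)))
            * s.station.r_b
            for s in dist.solutions
        ]
    )
    torque = float(np.trapezoid(dq, r))
    power = op.omega(planform.rotor_radius) * torque
    return power / (0.5 * op.rho * op.u_inf**3 * math.pi * planform.rotor_radius**2)
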