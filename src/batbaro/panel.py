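"""Hess–Smith panel method: incompressible potential flow around a section.

Constant-strength source panels plus a single vortex strength shared by all
panels, closed with the Kutta condition (equal and opposite tangential
velocities on the two trailing-edge panels).  Influence integrals are
evaluated with the complex-logarithm form of the constant source/vortex
panel, which yields the correct one-sided limit on the panel itself through
the principal branch.

The solver works in chord units with unit freestream; dimensional pressures
come from Bernoulli with the stored reference state,
``p = p_inf + 0.5 rho u_rel^2 (1 - |V/u_rel|^2)`` and
``cp = (p - p_inf) / (0.5 rho u_rel^2) = 1 - |V/u_rel|^2``.

This inviscid field is the desk-scale stand-in for a RANS computation of the
blade section; its known bias is an over-predicted suction peak at high
angle of attack (no viscous decambering), which is why downstream consumers
treat near-surface extrema as tolerance-banded quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .airfoil import AirfoilShape

__all__ = ["PanelSolution", "FieldSample", "PanelSolverError", "solve_panel", "surface_cp", "field_velocity", "field_pressure"]


class PanelSolverError(RuntimeError):
    """Raised when the panel system is singular (degenerate geometry)."""


@dataclass(frozen=True)
class FieldSample:
    """Velocity/pressure sample at one off-body point (meters and Pa)."""

    x: float
    y: float
    u: float
    v: float
    p: float
    cp: float
    inside: bool = False


@dataclass
class PanelSolution:
    """Solved panel system for one section at one flow state."""

    shape: AirfoilShape
    alpha: float  # deg
    u_rel: float  # m/s
    rho: float  # kg/m^3
    p_inf: float  # Pa
    chord_m: float  # physical chord of the section, m
    nodes: np.ndarray  # complex, chord units
    lengths: np.ndarray
    tangents: np.ndarray  # complex unit tangents
    midpoints: np.ndarray  # complex
    sources: np.ndarray  # per-panel source strengths
    vortex: float  # shared vortex strength
    vt_surface: np.ndarray  # tangential speed at panel midpoints (units of u_rel)
    circulation: float  # ccw circulation in chord units
    cl: float

    _polygon: Polygon | None = None

    @property
    def q_dyn(self) -> float:
        """Dynamic pressure 0.5 rho u_rel^2 (Pa)."""
        return 0.5 * self.rho * self.u_rel**2

    def polygon(self, in_meters: bool = True) -> Polygon:
        """Section contour as a shapely polygon (meters by default)."""
        if self._polygon is None:
            self._polygon = Polygon(np.column_stack([self.nodes.real, self.nodes.imag]))
        if in_meters and self.chord_m != 1.0:
            return Polygon(
                np.column_stack([self.nodes.real * self.chord_m, self.nodes.imag * self.chord_m])
            )
        return self._polygon


def _panel_geometry(shape: AirfoilShape) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nodes = shape.coords[:, 0] + 1j * shape.coords[:, 1]
    # drop consecutive duplicates (a closed TE repeats the first node)
    keep = np.ones(len(nodes), dtype=bool)
    keep[1:] = np.abs(np.diff(nodes)) > 1e-12
    nodes = nodes[keep]
    dz = np.diff(nodes)
    lengths = np.abs(dz)
    tangents = dz / lengths
    midpoints = 0.5 * (nodes[:-1] + nodes[1:])
    return nodes, lengths, tangents, midpoints


def _influence(points: np.ndarray, nodes: np.ndarray, lengths: np.ndarray, tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complex conjugate-velocity influence of unit source / unit vortex panels.

    Returns ``(S, V)`` of shape (n_points, n_panels): the conjugate velocity
    ``u - i v`` at each point due to each panel.
    """
    P = np.asarray(points, dtype=complex).reshape(-1, 1)
    Z = (P - nodes[:-1][None, :]) * np.conj(tangents)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.log(Z / (Z - lengths[None, :])) / (2.0 * math.pi)
    w = np.where(np.isfinite(w), w, 0.0)
    # points exactly on a panel (the collocation midpoints): take the
    # exterior-side limit, v = -q/2 along the local normal that points into
    # the body for the counterclockwise loop
    on_panel = (
        (np.abs(Z.imag) < 1e-12)
        & (Z.real > 1e-12)
        & (Z.real < lengths[None, :] - 1e-12)
    )
    w = np.where(on_panel, 0.5j, w)
    S = w * np.conj(tangents)[None, :]
    V = 1j * w * np.conj(tangents)[None, :]
    return S, V


def solve_panel(
    shape: AirfoilShape,
    alpha: float,
    u_rel: float = 1.0,
    rho: float = 1.225,
    p_inf: float = 101325.0,
    chord_m: float = 1.0,
) -> PanelSolution:
    """Solve the Hess–Smith system for ``shape`` at ``alpha`` degrees.

    ``u_rel``, ``rho``, ``p_inf`` and ``chord_m`` only set the dimensional
    reference state; the linear system itself is solved in chord units with a
    unit freestream.
    """
    if abs(alpha) >= 25.0:
        raise ValueError(f"|alpha| must be < 25 deg for an attached-flow model, got {alpha}")
    if u_rel <= 0:
        raise ValueError("u_rel must be positive")
    nodes, lengths, tangents, midpoints = _panel_geometry(shape)
    n = len(lengths)
    if n < 10:
        raise PanelSolverError("too few panels for a meaningful solution")

    S, V = _influence(midpoints, nodes, lengths, tangents)
    normals = -1j * tangents  # outward for the counterclockwise Selig loop

    a_rad = math.radians(alpha)
    w_inf = complex(math.cos(a_rad), -math.sin(a_rad))  # conj of unit freestream

    A = np.empty((n + 1, n + 1))
    b = np.empty(n + 1)
    # flow tangency at every panel midpoint
    A[:n, :n] = (S * normals[:, None]).real
    A[:n, n] = (V * normals[:, None]).real.sum(axis=1)
    b[:n] = -(w_inf * normals).real
    # Kutta closure on the two trailing-edge panels
    kutta_t = S[0, :] * tangents[0] + S[-1, :] * tangents[-1]
    A[n, :n] = kutta_t.real
    A[n, n] = (V[0, :] * tangents[0] + V[-1, :] * tangents[-1]).real.sum()
    b[n] = -(w_inf * (tangents[0] + tangents[-1])).real

    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise PanelSolverError("singular panel system (degenerate geometry?)") from exc
    if not np.all(np.isfinite(x)):
        raise PanelSolverError("non-finite panel solution")
    sources, vortex = x[:n], float(x[n])

    w_mid = w_inf + S @ sources + vortex * V.sum(axis=1)
    vt = (w_mid * tangents).real
    circulation = float(np.sum(vt * lengths))
    cl = -2.0 * circulation  # Kutta–Joukowski, unit freestream and chord

    return PanelSolution(
        shape=shape,
        alpha=alpha,
        u_rel=u_rel,
        rho=rho,
        p_inf=p_inf,
        chord_m=chord_m,
        nodes=nodes,
        lengths=lengths,
        tangents=tangents,
        midpoints=midpoints,
        sources=sources,
        vortex=vortex,
        vt_surface=vt,
        circulation=circulation,
        cl=cl,
    )


def surface_cp(sol: PanelSolution) -> np.ndarray:
    """Surface pressure coefficient, rows of ``(x/c, cp)`` at panel midpoints."""
    cp = 1.0 - sol.vt_surface**2
    return np.column_stack([sol.midpoints.real, cp])


def cl_from_cp(sol: PanelSolution) -> float:
    """Independent lift route: integrate surface cp over the contour."""
    normals = -1j * sol.tangents
    force = -np.sum((1.0 - sol.vt_surface**2) * normals * sol.lengths)  # complex force/chord
    a = math.radians(sol.alpha)
    lift_dir = complex(-math.sin(a), math.cos(a))
    return float((force.real * lift_dir.real) + (force.imag * lift_dir.imag))


def field_velocity(sol: PanelSolution, points: np.ndarray) -> np.ndarray:
    """Velocity (units of ``u_rel``) at off-body points given in chord units.

    ``points`` is (m, 2); returns (m, 2).
    """
    pts = np.asarray(points, dtype=float)
    z = pts[:, 0] + 1j * pts[:, 1]
    S, V = _influence(z, sol.nodes, sol.lengths, sol.tangents)
    a_rad = math.radians(sol.alpha)
    w = complex(math.cos(a_rad), -math.sin(a_rad)) + S @ sol.sources + sol.vortex * V.sum(axis=1)
    vel = np.conj(w)
    return np.column_stack([vel.real, vel.imag])


def field_pressure(sol: PanelSolution, points_m: np.ndarray) -> list[FieldSample]:
    """Pressure samples at points given in meters (section frame, LE at origin).

    Points that fall inside the contour are flagged (``inside=True``) rather
    than returned as silent garbage; their velocity/pressure values are NaN.
    """
    pts_m = np.atleast_2d(np.asarray(points_m, dtype=float))
    p, cp, vel, inside = pressure_at(sol, pts_m)
    out: list[FieldSample] = []
    for i in range(len(pts_m)):
        out.append(
            FieldSample(
                x=float(pts_m[i, 0]),
                y=float(pts_m[i, 1]),
                u=float(vel[i, 0]),
                v=float(vel[i, 1]),
                p=float(p[i]),
                cp=float(cp[i]),
                inside=bool(inside[i]),
            )
        )
    return out


def pressure_at(sol: PanelSolution, points_m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized field pressure at points in meters.

    Returns ``(p, cp, velocity_mps, inside_mask)``; inside points carry NaN.
    """
    pts_m = np.atleast_2d(np.asarray(points_m, dtype=float))
    pts_c = pts_m / sol.chord_m
    vel_unit = field_velocity(sol, pts_c)
    speed2 = np.sum(vel_unit**2, axis=1)
    cp = 1.0 - speed2
    p = sol.p_inf + sol.q_dyn * cp
    vel = vel_unit * sol.u_rel

    poly = sol.polygon(in_meters=False)
    inside = shapely.contains_xy(poly, pts_c[:, 0], pts_c[:, 1])
    if inside.any():
        p = p.copy()
        cp = cp.copy()
        vel = vel.copy()
        p[inside] = np.nan
        cp[inside] = np.nan
        vel[inside] = np.nan
    return p, cp, vel, inside
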