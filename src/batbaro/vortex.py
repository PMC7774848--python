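"""Blade-tip vortex model: Vatistas (n = 2) velocity and pressure profiles.

The tip vortex carries the maximum bound circulation of the blade
(``Gamma_vortex``) inside a viscous core of radius ``r_c``.  With
``rbar = r / r_c`` the swirl velocity is

    v_theta(rbar) = Gamma / (2 pi r_c) * rbar / sqrt(1 + rbar^4)

and integrating the radial momentum balance ``dp/dr = rho v_theta^2 / r``
with ``p -> p_inf`` far away gives the closed-form pressure profile

    p(r) - p_inf = rho Gamma^2 / (8 pi^2 r_c^2) * [atan(r^2/r_c^2) - pi/2]

whose minimum sits at the vortex center, ``p(0) - p_inf =
-rho Gamma^2 / (16 pi r_c^2)``.  The exponent n = 2 is the member of the
Vatistas family for which this integral is exact; the quadrature
self-consistency check in :mod:`batbaro.validation` enforces it.

The core radius follows the experimental correlation ``r_c = 0.05 * mean
chord``.  Viscous core growth downstream of the blade is exposed only as the
optional ``core_growth`` multiplier (default 1, i.e. the conservative
just-formed vortex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TipVortex", "core_radius", "tangential_velocity", "vortex_pressure", "radial_profile"]

#: Experimental core-radius fraction of the mean blade chord.
CORE_RADIUS_FRACTION = 0.05


@dataclass(frozen=True)
class TipVortex:
    """A rolled-up blade-tip vortex."""

    gamma_vortex: float  # circulation strength, m^2/s
    r_c: float  # core radius, m
    rho: float = 1.225  # kg/m^3
    core_growth: float = 1.0  # optional viscous-growth multiplier, >= 1

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError(f"core radius must be positive, got {self.r_c}")
        if self.gamma_vortex < 0:
            raise ValueError(f"vortex strength must be non-negative, got {self.gamma_vortex}")
        if self.core_growth < 1:
            raise ValueError(f"core growth multiplier must be >= 1, got {self.core_growth}")

    @property
    def effective_core_radius(self) -> float:
        return self.r_c * self.core_growth

    def center_pressure_deficit(self) -> float:
        """Magnitude of the pressure deficit at the vortex center (Pa)."""
        rc = self.effective_core_radius
        return self.rho * self.gamma_vortex**2 / (16.0 * math.pi * rc**2)


def core_radius(mean_chord: float, growth: float = 1.0) -> float:
    """Vortex core radius from the mean blade chord, ``r_c = 0.05 c * growth``."""
    if mean_chord <= 0:
        raise ValueError(f"mean chord must be positive, got {mean_chord}")
    if growth < 1:
        raise ValueError(f"growth multiplier must be >= 1, got {growth}")
    return CORE_RADIUS_FRACTION * mean_chord * growth


def tangential_velocity(r: float | np.ndarray, vortex: TipVortex) -> float | np.ndarray:
    """Swirl velocity ``v_theta`` (m/s) at radius ``r`` (m) from the center.

    Solid-body inside the core, free-vortex ``Gamma/(2 pi r)`` far outside,
    peaking at ``r = r_c`` with value ``Gamma / (2 pi r_c sqrt(2))``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    rc = vortex.effective_core_radius
    rbar = r / rc
    v = vortex.gamma_vortex / (2.0 * math.pi * rc) * rbar / np.sqrt(1.0 + rbar**4)
    return float(v) if v.ndim == 0 else v


def vortex_pressure(r: float | np.ndarray, vortex: TipVortex, p_inf: float = 101325.0) -> float | np.ndarray:
    """Absolute pressure (Pa) at radius ``r`` (m) from the vortex center."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    rc = vortex.effective_core_radius
    coeff = vortex.rho * vortex.gamma_vortex**2 / (8.0 * math.pi**2 * rc**2)
    p = p_inf + coeff * (np.arctan((r / rc) ** 2) - math.pi / 2.0)
    return float(p) if p.ndim == 0 else p


def radial_profile(vortex: TipVortex, r_max: float, n: int = 500, p_inf: float = 101325.0) -> np.ndarray:
    """Radial profile rows ``(r_m, v_theta_mps, dp_Pa)`` out to ``r_max``."""
    r = np.linspace(0.0, r_max, n)
    return np.column_stack([r, tangential_velocity(r, vortex), vortex_pressure(r, vortex, p_inf) - p_inf])
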