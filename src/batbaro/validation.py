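"""Analytic validation oracles for the numerical stages.

Each check compares a numerical route against an independent closed-form
solution:

* the vortex pressure profile against direct quadrature of the radial
  momentum balance (confirming the closed-form integral, and with it the
  swirl-law exponent);
* the panel method against the exact conformal-map (Joukowski) solution and
  the thin-airfoil lift slope;
* the blade-element solution against the Betz limit on an ideal rotor.

These run from the ``validate`` CLI command and are reused by the test
suite.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .airfoil import AirfoilShape
from .panel import solve_panel
from .vortex import TipVortex, tangential_velocity, vortex_pressure

__all__ = [
    "vortex_quadrature_error",
    "joukowski_shape_and_speed",
    "joukowski_surface_speed_rms",
    "betz_margin",
    "run_all",
]


def vortex_quadrature_error(vortex: TipVortex | None = None, rbar_max: float = 50.0, n_check: int = 40) -> float:
    """Max relative error of the closed-form vortex pressure vs quadrature.

    Integrates ``dp/dr = rho v_theta^2 / r`` numerically from each check
    radius to a far radius and compares the pressure drop with the
    closed-form profile; the error is normalized by the center deficit.
    """
    vortex = vortex or TipVortex(gamma_vortex=73.5, r_c=0.17)
    rc = vortex.effective_core_radius
    r_far = 200.0 * rc
    scale = vortex.center_pressure_deficit()

    def dpdr(r: float) -> float:
        if r == 0:
            return 0.0
        v = float(tangential_velocity(r, vortex))
        return vortex.rho * v * v / r

    p_far = float(vortex_pressure(r_far, vortex, p_inf=0.0))
    worst = 0.0
    for rbar in np.linspace(0.0, rbar_max, n_check):
        r = rbar * rc
        integral, _ = quad(dpdr, r, r_far, limit=400, epsabs=1e-12, epsrel=1e-12)
        p_quad = p_far - integral
        p_closed = float(vortex_pressure(r, vortex, p_inf=0.0))
        worst = max(worst, abs(p_quad - p_closed) / scale)
    return worst


@dataclass(frozen=True)
class ConformalCase:
    """A Joukowski-family airfoil with its exact surface-speed distribution."""

    shape: AirfoilShape
    alpha: float
    theta_mid: np.ndarray
    exact_speed: np.ndarray  # |velocity| / U at the mapped theta midpoints


def joukowski_shape_and_speed(
    alpha_deg: float = 5.0,
    mu: complex = complex(-0.08, 0.05),
    n_panels: int = 240,
    te_exponent: float = 1.9,
) -> ConformalCase:
    """Exact conformal-map flow around a Joukowski-family airfoil.

    The circle of radius ``R = |1 - mu|`` about ``mu`` maps through the
    Kármán–Trefftz transform ``z = k (f+ + f-)/(f+ - f-)`` with
    ``f± = (zeta ± 1)^k`` to an airfoil with trailing-edge angle
    ``(2 - k) pi``; ``k = 2`` recovers the classical cusped Joukowski shape.
    The default ``k = 1.9`` (18° trailing edge) keeps the exact solution of
    the same family while avoiding the cusp, at which the discrete Kutta
    closure of any low-order panel method degenerates and converges only at
    first order.  The circulation is fixed by a stagnation point at the
    trailing-edge preimage (the Kutta condition in closed form); surface
    speeds are returned at the panel-midpoint preimages, normalized by the
    freestream.
    """
    R = abs(1.0 - mu)
    k = te_exponent
    a = math.radians(alpha_deg)
    theta_te = cmath.phase(1.0 - mu)
    # circulation from the exact trailing-edge stagnation condition (circle plane)
    gamma = (
        2.0 * math.pi * (1.0 - mu) * (cmath.exp(-1j * a) - R**2 * cmath.exp(1j * a) / (1.0 - mu) ** 2) / 1j
    )
    gamma = gamma.real  # imaginary part is zero to round-off

    def kt_map(zeta: np.ndarray) -> np.ndarray:
        w = ((zeta - 1.0) / (zeta + 1.0)) ** k
        return k * (1.0 + w) / (1.0 - w)

    def kt_deriv(zeta: np.ndarray) -> np.ndarray:
        fp = (zeta + 1.0) ** k
        fm = (zeta - 1.0) ** k
        return 4.0 * k**2 * (zeta**2 - 1.0) ** (k - 1.0) / (fp - fm) ** 2

    theta_nodes = theta_te + np.linspace(0.0, 2.0 * math.pi, n_panels + 1)
    z_nodes = kt_map(mu + R * np.exp(1j * theta_nodes[:-1]))
    z_nodes = np.append(z_nodes, z_nodes[0])  # close the loop exactly

    # normalize to unit chord for the panel solver (scale-invariant flow)
    x = z_nodes.real
    xmin, xmax = x.min(), x.max()
    scale = xmax - xmin
    coords = np.column_stack([(x - xmin) / scale, z_nodes.imag / scale])
    shape = AirfoilShape(name="karman-trefftz", coords=coords, closed_te=True)

    theta_mid = 0.5 * (theta_nodes[:-1] + theta_nodes[1:])
    zeta_m = mu + R * np.exp(1j * theta_mid)
    dF = (
        np.exp(-1j * a)
        - R**2 * np.exp(1j * a) / (zeta_m - mu) ** 2
        - 1j * gamma / (2.0 * math.pi * (zeta_m - mu))
    )
    speed = np.abs(dF / kt_deriv(zeta_m))
    return ConformalCase(shape=shape, alpha=alpha_deg, theta_mid=theta_mid, exact_speed=speed)


def joukowski_surface_speed_rms(alpha_deg: float = 5.0, n_panels: int = 240) -> float:
    """RMS surface-speed error of the panel method vs the exact solution."""
    case = joukowski_shape_and_speed(alpha_deg=alpha_deg, n_panels=n_panels)
    sol = solve_panel(case.shape, case.alpha)
    err = np.abs(sol.vt_surface) - case.exact_speed
    return float(np.sqrt(np.mean(err**2)))


def betz_margin(tsr: float = 7.0, u_inf: float = 8.0) -> tuple[float, float]:
    """Power coefficient of the ideal toy rotor and the Betz limit."""
    from .bem import power_coefficient
    from .fixtures import toy_rotor
    from .geometry import OperatingPoint

    planform, polars = toy_rotor(n_stations=15)
    cp = power_coefficient(planform, OperatingPoint(u_inf=u_inf, tsr=tsr), polars)
    return cp, 16.0 / 27.0


def run_all(verbose: bool = True) -> dict[str, float]:
    """Run every oracle; returns the measured figures of merit."""
    quad_err = vortex_quadrature_error()
    rms = joukowski_surface_speed_rms()
    cp, betz = betz_margin()
    results = {
        "vortex_quadrature_max_rel_error": quad_err,
        "joukowski_surface_speed_rms": rms,
        "toy_rotor_cp": cp,
        "betz_limit": betz,
    }
    if verbose:
        print(f"vortex pressure vs quadrature: max relative error {quad_err:.3e} (tolerance 1e-6)")
        print(f"panel method vs Joukowski exact: surface-speed RMS {rms:.4f} of freestream (tolerance 0.01)")
        print(f"ideal-rotor power coefficient {cp:.4f} vs Betz limit {betz:.4f}")
    return results
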