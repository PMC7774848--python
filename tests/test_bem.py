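"""Blade-element momentum solution and the bound-circulation chain."""

import math

import numpy as np
import pytest

from batbaro.bem import (
    circulation_from_lift,
    power_coefficient,
    solve_bem_section,
    spanwise_circulation,
    tip_vortex_strength,
)
from batbaro.fixtures import toy_rotor
from batbaro.geometry import OperatingPoint, operating_point_for
from batbaro.vortex import TipVortex, vortex_pressure


class TestCirculationFromLift:
    def test_zero_lift(self):
        assert circulation_from_lift(0.0, 1.225, 50.0) == 0.0

    def test_hand_arithmetic(self):
        assert circulation_from_lift(1000.0, 1.225, 50.0) == pytest.approx(16.33, abs=0.005)

    def test_density_scaling_exact(self):
        g = circulation_from_lift(1000.0, 1.225, 50.0)
        assert circulation_from_lift(1000.0, 2.45, 50.0) == pytest.approx(g / 2.0, rel=1e-15)

    @pytest.mark.parametrize("v", [0.0, -1.0])
    def test_invalid_speed(self, v):
        with pytest.raises(ValueError):
            circulation_from_lift(1.0, 1.225, v)

    def test_strength_inverted_from_vortex_center_pressure(self):
        # algebraic inversion of the center-pressure formula: the strength
        # that produces a 4556 Pa deficit with r_c = 0.17 m
        r_c, rho, deficit = 0.17, 1.225, 4556.0
        gamma = math.sqrt(deficit * 16.0 * math.pi * r_c**2 / rho)
        assert gamma == pytest.approx(73.5, abs=0.1)
        tv = TipVortex(gamma_vortex=gamma, r_c=r_c, rho=rho)
        assert vortex_pressure(0.0, tv, p_inf=0.0) == pytest.approx(-deficit, rel=1e-12)


class TestSolveBemSection:
    def test_toy_rotor_matches_grid_search(self):
        # independent oracle: brute-force minimization of the momentum /
        # blade-element balance residual over the (a, a') plane.  The toy is
        # lightly loaded (small chord, moderate tip-speed ratio) so the
        # solution stays below the high-induction branch and the pure
        # momentum balance is the complete description.
        plan, polars = toy_rotor(n_stations=9, chord=0.25)
        op = OperatingPoint(u_inf=8.0, tsr=5.0)
        stn = plan.stations[4]
        sol = solve_bem_section(plan, op, stn, polars["ideal"])

        B, R, r = plan.n_blades, plan.rotor_radius, stn.r_b
        omega = op.omega(R)
        sigma = B * stn.chord / (2 * math.pi * r)

        def residual(a, at):
            phi = math.atan2(op.u_inf * (1 - a), omega * r * (1 + at))
            alpha = math.degrees(phi) - stn.twist
            cl = 2 * math.pi * math.sin(math.radians(alpha))
            cn = cl * math.cos(phi)
            ct = cl * math.sin(phi)
            f_tip = B * (R - r) / (2 * r * math.sin(phi))
            F = (2 / math.pi) * math.acos(min(1.0, math.exp(-f_tip)))
            r1 = a / (1 - a) - sigma * cn / (4 * F * math.sin(phi) ** 2)
            r2 = at / (1 + at) - sigma * ct / (4 * F * math.sin(phi) * math.cos(phi))
            return r1 * r1 + r2 * r2

        grid_a = np.linspace(0.0, 0.6, 601)
        grid_at = np.linspace(-0.01, 0.05, 121)
        res = [[residual(a, at) for at in grid_at] for a in grid_a]
        i, j = np.unravel_index(np.argmin(res), (len(grid_a), len(grid_at)))
        assert sol.a == pytest.approx(grid_a[i], abs=2e-3)
        assert sol.a_tan == pytest.approx(grid_at[j], abs=1e-3)

    def test_reference_rotor_converges_at_all_stations(self, fixture_set):
        op = operating_point_for(10.0)
        dist = spanwise_circulation(fixture_set.planform, op, fixture_set.polars)
        for s in dist.solutions:
            assert 0.0 < s.a < 0.5
            assert s.residual < 1e-8

    def test_zero_wind_rejected(self, fixture_set):
        with pytest.raises(ValueError):
            OperatingPoint(u_inf=0.0, tsr=7.0)

    def test_gamma_equals_half_c_cl_v_two_routes(self, fixture_set):
        # Kutta-Joukowski route (L'/(rho v)) vs geometric route (c Cl v / 2)
        op = operating_point_for(10.0)
        dist = spanwise_circulation(fixture_set.planform, op, fixture_set.polars)
        for s in dist.solutions:
            assert s.gamma == pytest.approx(0.5 * s.station.chord * s.cl * s.v, rel=1e-10, abs=1e-12)


class TestSpanwiseCirculation:
    def test_single_outboard_peak(self, fixture_set):
        dist = spanwise_circulation(fixture_set.planform, operating_point_for(10.0), fixture_set.polars)
        R = fixture_set.planform.rotor_radius
        assert 0.3 * R < dist.r_at_max < 0.95 * R
        gammas = np.array([g for _, g in dist.points])
        peak = float(gammas.max())
        # broadly single-peaked: small near the (cylindrical) root, reduced
        # at the tip by the Prandtl loss factor; station-to-station jiggle
        # from airfoil-family changes stays within a few percent
        assert np.all(gammas[:3] < 0.1 * peak)
        assert gammas[-1] < 0.75 * peak
        i_peak = int(np.argmax(gammas))
        assert np.all(np.diff(gammas[3 : i_peak + 1]) > -0.05 * peak)
        assert np.all(np.diff(gammas[i_peak:]) < 0.05 * peak)

    def test_toy_rotor_closed_form_per_station(self):
        plan, polars = toy_rotor(n_stations=7, chord=0.8)
        op = OperatingPoint(u_inf=8.0, tsr=7.0)
        dist = spanwise_circulation(plan, op, polars)
        for s in dist.solutions:
            # closed-form polar evaluated independently of the tabulated
            # interpolation the solver uses (0.5 deg table -> ~1e-5 agreement)
            cl_expected = 2 * math.pi * math.sin(math.radians(s.alpha))
            assert s.gamma == pytest.approx(0.5 * 0.8 * cl_expected * s.v, rel=1e-4)

    def test_zero_lift_polar_gives_zero_circulation(self):
        plan, polars = toy_rotor(zero_lift=True)
        dist = spanwise_circulation(plan, OperatingPoint(u_inf=8.0, tsr=7.0), polars)
        assert all(g == 0.0 for _, g in dist.points)


class TestTipVortexStrength:
    def test_triangular_profile(self):
        from batbaro.bem import SpanwiseCirculation

        dist = SpanwiseCirculation(points=((1.0, 10.0), (2.0, 50.0), (3.0, 20.0)), solutions=())
        assert tip_vortex_strength(dist) == 50.0
        assert dist.r_at_max == 2.0

    def test_equals_linear_scan(self, fixture_set):
        dist = spanwise_circulation(fixture_set.planform, operating_point_for(10.0), fixture_set.polars)
        best = -np.inf
        for _, g in dist.points:
            best = g if g > best else best
        assert tip_vortex_strength(dist) == best

    def test_strength_grows_with_wind_speed(self, fixture_set):
        strengths = [
            tip_vortex_strength(
                spanwise_circulation(fixture_set.planform, operating_point_for(u), fixture_set.polars)
            )
            for u in (5.0, 7.5, 10.0)
        ]
        assert strengths[0] < strengths[1] < strengths[2]

    def test_empty_distribution_rejected(self):
        from batbaro.bem import SpanwiseCirculation

        with pytest.raises(ValueError):
            SpanwiseCirculation(points=(), solutions=())


def test_toy_rotor_respects_betz_limit():
    plan, polars = toy_rotor(n_stations=15)
    for tsr in (6.0, 7.0, 8.0):
        cp = power_coefficient(plan, OperatingPoint(u_inf=8.0, tsr=tsr), polars)
        assert 0.0 < cp <= 16.0 / 27.0 + 1e-6
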