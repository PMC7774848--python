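"""Planform, operating schedule and section kinematics."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from batbaro.fixtures import data_path
from batbaro.geometry import (
    BladePlanform,
    OperatingEnvelopeError,
    OperatingPoint,
    PlanformError,
    PlanformStation,
    load_planform,
    mean_chord,
    operating_point_for,
    section_at_fraction,
    section_kinematics,
)


def station(r, chord=1.0, twist=0.0):
    return PlanformStation(r_b=r, chord=chord, twist=twist, airfoil_id="x", thickness_ratio=0.2)


class TestLoadPlanform:
    def test_reference_fixture(self, fixture_set):
        plan = fixture_set.planform
        assert plan.rotor_radius == 63.0
        assert plan.n_blades == 3
        assert len(plan.stations) == 17

    def test_two_station_toy(self):
        plan = load_planform([station(1.0), station(2.0)])
        assert plan.rotor_radius == 2.0
        assert [s.r_b for s in plan.stations] == [1.0, 2.0]

    def test_out_of_order_input_is_sorted_then_validated(self):
        # unsorted records are sorted; duplicates rejected
        plan = load_planform([station(2.0), station(1.0)])
        assert [s.r_b for s in plan.stations] == [1.0, 2.0]
        with pytest.raises(PlanformError):
            load_planform([station(1.0), station(1.0)])

    def test_non_monotone_stations_rejected(self):
        with pytest.raises(PlanformError):
            BladePlanform(
                stations=(station(2.0), station(1.0)),
                rotor_radius=3.0,
                hub_radius=0.0,
                n_blades=3,
            )

    def test_non_positive_chord_rejected(self):
        with pytest.raises(PlanformError):
            station(1.0, chord=0.0)

    def test_too_few_stations_rejected(self):
        with pytest.raises(PlanformError):
            load_planform([station(1.0)])


class TestMeanChord:
    def test_reference_mean_chord_gives_core_radius(self, fixture_set):
        # 0.05 * mean chord reproduces the 0.17 m tip-vortex core radius
        assert 0.05 * mean_chord(fixture_set.planform) == pytest.approx(0.17, abs=0.005)

    def test_against_independent_column_sum(self, fixture_set):
        # brute-force oracle: re-read the delimited fixture with pandas
        df = pd.read_csv(data_path("nrel5mw_planform.csv"), comment="#")
        assert mean_chord(fixture_set.planform) == pytest.approx(df["chord_m"].mean(), rel=1e-12)

    def test_uniform_chord(self):
        plan = load_planform([station(r, chord=1.7) for r in (1.0, 2.0, 3.0)])
        assert mean_chord(plan) == pytest.approx(1.7)

    @given(st.permutations(range(5)))
    def test_order_independent(self, perm):
        chords = [1.0, 2.0, 3.5, 0.7, 1.1]
        radii = [1.0, 2.0, 3.0, 4.0, 5.0]
        plan = load_planform([station(radii[i], chords[i]) for i in perm])
        assert mean_chord(plan) == pytest.approx(np.mean(chords))


class TestSectionAtFraction:
    def test_90_percent_span_chord(self, fixture_set):
        st90 = section_at_fraction(fixture_set.planform, 0.90)
        assert st90.chord == pytest.approx(2.31, abs=0.005)
        assert st90.airfoil_id == "naca64_a17"
        assert st90.thickness_ratio == pytest.approx(0.17)

    def test_boundary_is_outermost(self, fixture_set):
        assert section_at_fraction(fixture_set.planform, 1.0) is fixture_set.planform.stations[-1]

    def test_against_linear_scan(self, fixture_set):
        plan = fixture_set.planform
        target = 0.5 * plan.rotor_radius
        best = min(plan.stations, key=lambda s: abs(s.r_b - target))
        assert section_at_fraction(plan, 0.5) is best

    @pytest.mark.parametrize("f", [0.0, -0.1, 1.2])
    def test_invalid_fraction(self, fixture_set, f):
        with pytest.raises(ValueError):
            section_at_fraction(fixture_set.planform, f)


class TestOperatingSchedule:
    @pytest.mark.parametrize(
        "u,tsr,pitch", [(5.0, 10.0, 0.0), (7.5, 7.7, 0.0), (10.0, 7.6, 0.0)]
    )
    def test_scheduled_rows_exact(self, u, tsr, pitch):
        op = operating_point_for(u)
        assert (op.tsr, op.pitch) == (tsr, pitch)
        # idempotent: asking again gives the identical state
        assert operating_point_for(u) == op

    def test_interpolates_between_rows(self):
        op = operating_point_for(6.25)
        assert 7.7 < op.tsr < 10.0

    @pytest.mark.parametrize("u", [2.0, 30.0])
    def test_outside_envelope(self, u):
        with pytest.raises(OperatingEnvelopeError):
            operating_point_for(u)

    def test_rotor_speed_follows_tsr(self):
        op = operating_point_for(10.0)
        assert op.omega(63.0) == pytest.approx(7.6 * 10.0 / 63.0)

    def test_rated_tip_speed_representable(self):
        # rated state: 11.4 m/s wind, 12.1 rpm -> ~80 m/s tip speed
        omega_rated = 12.1 * 2 * math.pi / 60.0
        op = OperatingPoint(u_inf=11.4, tsr=omega_rated * 63.0 / 11.4)
        assert op.omega(63.0) * 63.0 == pytest.approx(80.0, rel=0.005)
        # cut-in state: 3 m/s wind, 6.9 rpm
        omega_ci = 6.9 * 2 * math.pi / 60.0
        assert OperatingPoint(u_inf=3.0, tsr=omega_ci * 63.0 / 3.0).tsr > 0


class TestSectionKinematics:
    def test_hand_arithmetic(self):
        # 5 m/s, TSR 10, f = 0.9, a = 1/3: sqrt(45^2 + 3.333^2)
        op = operating_point_for(5.0)
        u_rel, phi = section_kinematics(op, 0.9, 1.0 / 3.0, 0.0, rotor_radius=63.0)
        assert u_rel == pytest.approx(math.hypot(45.0, 5.0 * 2.0 / 3.0), rel=1e-12)
        assert u_rel == pytest.approx(45.12, abs=0.01)

    def test_degenerate_axial_only(self):
        # zero tangential speed: relative wind is the axial inflow, phi = 90 deg
        op = operating_point_for(5.0)
        u_rel, phi = section_kinematics(op, 1e-12, 0.0, 0.0, rotor_radius=63.0)
        assert u_rel == pytest.approx(5.0, rel=1e-6)
        assert phi == pytest.approx(90.0, abs=1e-3)

    def test_monotone_in_span_fraction(self):
        op = operating_point_for(10.0)
        fs = np.linspace(0.1, 1.0, 20)
        u = [section_kinematics(op, f, 0.3, 0.01, rotor_radius=63.0)[0] for f in fs]
        assert np.all(np.diff(u) > 0)

    def test_invalid_induction(self):
        op = operating_point_for(10.0)
        with pytest.raises(ValueError):
            section_kinematics(op, 0.9, 1.0, 0.0, rotor_radius=63.0)
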