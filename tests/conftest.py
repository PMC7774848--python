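import numpy as np
import pytest
from hypothesis import settings

from batbaro.exposure import exposure_summary
from batbaro.fixtures import reference_fixture_set
from batbaro.geometry import operating_point_for, section_at_fraction, section_state_for
from batbaro.panel import solve_panel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_set():
    return reference_fixture_set()


@pytest.fixture(scope="session")
def sol10(fixture_set):
    """Panel solution of the 90%-span section at the 10 m/s operating state."""
    u_rel, alpha = section_state_for(10.0)
    op = operating_point_for(10.0)
    station = section_at_fraction(fixture_set.planform, 0.9)
    return solve_panel(
        fixture_set.section_shape,
        alpha,
        u_rel=u_rel,
        rho=op.rho,
        p_inf=op.p_inf,
        chord_m=station.chord,
    )


@pytest.fixture(scope="session")
def summary(fixture_set):
    """Full three-wind-speed exposure summary at the canonical +-10 m/s
    flight speed (the condition that realizes the published table's extrema)."""
    return exposure_summary(
        [5.0, 7.5, 10.0],
        fixture_set.planform,
        fixture_set.polars,
        fixture_set.section_shape,
    )
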