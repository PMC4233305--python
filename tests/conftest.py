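"""Shared fixtures: calibrated model objects and a few simulated beats.

Organ-level beats cost a couple of seconds each, so every run used by
more than one test lives in a session-scoped fixture.
"""

import pytest

from takolv.calcium import default_transients, make_transient
from takolv.contraction import default_contraction_params
from takolv.gradients import GradientSpec, MechanismConfig
from takolv.hemodynamics import default_windkessel
from takolv.ventricle import baseline_cycle, default_geometry, run_cycle


@pytest.fixture(scope="session")
def transient_params():
    return default_transients()


@pytest.fixture(scope="session")
def control_transient(transient_params):
    return make_transient(transient_params[0], dt=0.05)


@pytest.fixture(scope="session")
def stimulated_transient(transient_params):
    return make_transient(transient_params[1], dt=0.05)


@pytest.fixture(scope="session")
def cell_params():
    return default_contraction_params()


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def hemo():
    return default_windkessel()


@pytest.fixture(scope="session")
def baseline_result(geometry, hemo):
    result = baseline_cycle(geometry=geometry, hemo=hemo)
    assert result.status == "ok"
    return result


@pytest.fixture(scope="session")
def tension_mechanism_results(geometry, hemo):
    """Sharp-gradient maximum-tension runs at apical T_ref 30/60/90 kPa."""
    out = {}
    for t_ref_apex in (30.0, 60.0, 90.0):
        config = MechanismConfig(
            mechanism="tension",
            gradient=GradientSpec(0.5, 0.5),
            t_ref_apex=t_ref_apex,
            ca_t50_homog=0.9,
        )
        result = run_cycle(config, geometry=geometry, hemo=hemo)
        assert result.status == "ok"
        out[t_ref_apex] = result
    return out
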