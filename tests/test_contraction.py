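"""Two-state contraction model: kinetics, steady state, twitch, calibration."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from takolv.calcium import TransientParams, make_transient
from takolv.contraction import (
    CA50_FLOOR,
    ContractionParams,
    ContractionState,
    TwitchTrace,
    active_tension,
    ca50_of_stretch,
    calibrate_rates,
    simulate_isometric_twitch,
    steady_force_ca_curve,
    step_state,
    twitch_metrics,
)


@pytest.fixture(scope="module")
def simple_params():
    return ContractionParams(
        t_ref=120.0, ca_t50_ref=1.0, k_xb=0.02, k_trpn=0.1,
        n_trpn=2.0, n_xb=2.0, beta1=-1.5,
    )


class TestCa50OfStretch:
    def test_reference_length(self, simple_params):
        assert ca50_of_stretch(simple_params, 1.0) == pytest.approx(1.0)

    def test_no_length_dependence_when_beta1_zero(self, simple_params):
        p = replace(simple_params, beta1=0.0)
        for lam in (0.8, 1.0, 1.3):
            assert ca50_of_stretch(p, lam) == pytest.approx(p.ca_t50_ref)

    def test_stated_slope(self, simple_params):
        assert ca50_of_stretch(simple_params, 1.1) == pytest.approx(0.85)

    def test_floor_prevents_sign_change(self, simple_params):
        assert ca50_of_stretch(simple_params, 3.0) == pytest.approx(
            CA50_FLOOR * simple_params.ca_t50_ref
        )

    def test_stretch_monotonically_sensitizes_until_floor(self, simple_params):
        lams = np.linspace(1.0, 1.5, 40)
        vals = np.array([ca50_of_stretch(simple_params, l) for l in lams])
        above_floor = vals > CA50_FLOOR * simple_params.ca_t50_ref
        assert np.all(np.diff(vals[above_floor]) < 0)


class TestStepState:
    def test_rest_is_absorbing_without_calcium(self, simple_params):
        state = ContractionState(0.0, 0.0)
        out = step_state(state, ca=0.0, lam=1.0, params=simple_params, dt=0.1)
        assert out.trpn == 0.0 and out.xb == 0.0

    def test_saturating_calcium_drives_full_activation(self, simple_params):
        state = ContractionState(0.0, 0.0)
        for _ in range(20000):
            state = step_state(state, ca=100.0, lam=1.0, params=simple_params, dt=0.5)
        assert state.trpn == pytest.approx(1.0, abs=1e-3)
        assert state.xb == pytest.approx(1.0, abs=1e-3)

    def test_single_step_matches_refined_integration(self, simple_params):
        """One dt=0.01 step against an explicit-Euler oracle at dt=1e-4."""
        ca = ca50_of_stretch(simple_params, 1.0)
        trpn, xb = 0.5, 0.2
        n = 100
        h = 0.01 / n
        for _ in range(n):
            phi = (ca / ca) ** simple_params.n_trpn
            dtrpn = simple_params.k_trpn * (phi * (1 - trpn) - trpn)
            dxb = simple_params.k_xb * (trpn**simple_params.n_xb - xb)
            trpn += h * dtrpn
            xb += h * dxb
        out = step_state(
            ContractionState(0.5, 0.2), ca=ca, lam=1.0, params=simple_params, dt=0.01
        )
        assert out.trpn == pytest.approx(trpn, abs=1e-6)
        assert out.xb == pytest.approx(xb, abs=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(
        ca=st.floats(0.0, 10.0),
        lam=st.floats(0.7, 1.4),
        trpn=st.floats(0.0, 1.0),
        xb=st.floats(0.0, 1.0),
        dt=st.floats(0.01, 0.5),
    )
    def test_state_stays_in_unit_box(self, simple_params, ca, lam, trpn, xb, dt):
        out = step_state(ContractionState(trpn, xb), ca, lam, simple_params, dt)
        assert 0.0 <= out.trpn <= 1.0
        assert 0.0 <= out.xb <= 1.0


class TestActiveTension:
    def test_zero_crossbridges_zero_tension(self, simple_params):
        assert active_tension(ContractionState(0.3, 0.0), simple_params) == 0.0

    @pytest.mark.parametrize(
        "t_ref,expected", [(120.0, 120.0), (30.0, 30.0), (60.0, 60.0)]
    )
    def test_full_recruitment_gives_t_ref(self, simple_params, t_ref, expected):
        p = replace(simple_params, t_ref=t_ref)
        assert active_tension(ContractionState(1.0, 1.0), p) == pytest.approx(expected)

    def test_t_ref_30_is_75_percent_inhibition(self, simple_params):
        normal = active_tension(ContractionState(1.0, 1.0), simple_params)
        inhibited = active_tension(
            ContractionState(1.0, 1.0), replace(simple_params, t_ref=30.0)
        )
        assert inhibited / normal == pytest.approx(0.25)


def brute_force_ec50(params, lam=1.0, n_grid=10_000):
    """Oracle: closed-form fixed points on a dense calcium grid.

    Steady state: trpn = phi/(1+phi), xb = trpn**n_xb with
    phi = (ca/ca50)**n_trpn; EC50 is where tension crosses half its
    saturating value.
    """
    ca50 = ca50_of_stretch(params, lam)
    ca = np.linspace(1e-4, 50 * ca50, n_grid)
    phi = (ca / ca50) ** params.n_trpn
    tension = params.t_ref * (phi / (1 + phi)) ** params.n_xb
    half = 0.5 * params.t_ref
    idx = int(np.searchsorted(tension, half))
    x0, x1 = ca[idx - 1], ca[idx]
    y0, y1 = tension[idx - 1], tension[idx]
    return x0 + (half - y0) * (x1 - x0) / (y1 - y0)


class TestSteadyForceCaCurve:
    def test_ec50_matches_grid_scan_oracle(self, simple_params):
        curve = steady_force_ca_curve(simple_params)
        assert curve.ec50 == pytest.approx(brute_force_ec50(simple_params), rel=1e-3)

    def test_plateau_is_t_ref(self, simple_params):
        curve = steady_force_ca_curve(simple_params)
        assert curve.t_max == pytest.approx(simple_params.t_ref, rel=1e-4)

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 3.0])
    def test_ec50_proportional_to_ca_t50(self, simple_params, alpha):
        base = steady_force_ca_curve(simple_params).ec50
        scaled = steady_force_ca_curve(
            replace(simple_params, ca_t50_ref=alpha * simple_params.ca_t50_ref)
        ).ec50
        assert scaled == pytest.approx(alpha * base, rel=1e-6)

    def test_steady_tension_monotone_in_calcium_and_sensitivity(self, simple_params):
        ca50 = simple_params.ca_t50_ref
        ca = np.linspace(0.05, 5.0, 50)
        phi = (ca / ca50) ** simple_params.n_trpn
        tension = (phi / (1 + phi)) ** simple_params.n_xb
        assert np.all(np.diff(tension) > 0)
        desensitized = replace(simple_params, ca_t50_ref=2 * ca50)
        assert steady_force_ca_curve(desensitized).ec50 > steady_force_ca_curve(
            simple_params
        ).ec50


class TestTwitch:
    def test_unstimulated_cell_generates_negligible_tension(self, cell_params):
        p = TransientParams(c_dia=0.01, c_amp=1e-6, tau_rise=8, tau_decay=28)
        trace = simulate_isometric_twitch(cell_params, make_transient(p))
        assert trace.tension.max() < 0.01 * cell_params.t_ref

    def test_stimulated_twitch_stronger_than_control(
        self, cell_params, control_transient, stimulated_transient
    ):
        control = simulate_isometric_twitch(cell_params, control_transient)
        stimulated = simulate_isometric_twitch(cell_params, stimulated_transient)
        assert stimulated.tension.max() > control.tension.max()

    def test_refined_time_step_changes_peak_little(
        self, cell_params, control_transient
    ):
        coarse = simulate_isometric_twitch(cell_params, control_transient, dt=0.1)
        fine = simulate_isometric_twitch(cell_params, control_transient, dt=0.001)
        assert coarse.tension.max() == pytest.approx(
            fine.tension.max(), rel=1e-4
        )


class TestTwitchMetrics:
    @staticmethod
    def triangle(t_peak=40.0, t_end=100.0, dt=0.5, peak=10.0):
        times = np.arange(0.0, t_end + dt, dt)
        up = times / t_peak * peak
        down = (t_end - times) / (t_end - t_peak) * peak
        return TwitchTrace(times=times, tension=np.minimum(up, down))

    def test_ttp_of_triangular_trace(self):
        m = twitch_metrics(self.triangle())
        assert m.ttp == pytest.approx(40.0)

    def test_rt50_of_triangular_trace(self):
        # linear descent from 40 to 100 ms: half height at 70 ms
        m = twitch_metrics(self.triangle())
        assert m.rt50 == pytest.approx(30.0)

    def test_monotone_trace_raises(self):
        times = np.arange(0.0, 50.0, 1.0)
        with pytest.raises(ValueError, match="peak"):
            twitch_metrics(TwitchTrace(times=times, tension=times.copy()))

    def test_calibrated_control_twitch_within_experimental_ranges(
        self, cell_params, control_transient
    ):
        m = twitch_metrics(simulate_isometric_twitch(cell_params, control_transient))
        assert 33.0 <= m.ttp <= 45.0  # 39 +/- 6 ms
        assert 26.0 <= m.rt50 <= 36.0  # 31 +/- 5 ms


class TestCalibration:
    def test_calibrated_parameters_reproduce_targets(self, control_transient):
        fitted = calibrate_rates(control_transient)
        assert fitted.k_xb == 0.02
        m = twitch_metrics(simulate_isometric_twitch(fitted, control_transient))
        assert m.ttp == pytest.approx(39.0, abs=2.0)
        assert m.rt50 == pytest.approx(31.0, abs=5.0)
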