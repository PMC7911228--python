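"""Membrane dynamics: exactness of the stepper against the closed form,
threshold/reset behaviour, refractoriness and rheobase."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snnlab import (LIFParams, NeuronState, closed_form_potential, rheobase,
                    simulate_constant_current, step, time_to_first_spike)


def _run_steps(params, u0, I, dt, n):
    state = NeuronState(u=u0)
    out = [u0]
    for k in range(n):
        state = step(state, params, I, dt, now=k * dt)
        out.append(state.u)
    return np.array(out), state


class TestMembraneRelaxation:
    def test_rest_is_a_fixed_point(self, lif_defaults):
        traj, state = _run_steps(lif_defaults, -70.0, 0.0, 0.5, 200)
        assert np.all(traj == -70.0)
        assert state.spikes == []

    def test_relaxes_to_rest_from_any_subthreshold_start(self, lif_defaults):
        for u0 in (-60.0, -55.5, -90.0):
            _, state = _run_steps(lif_defaults, u0, 0.0, 0.1, 3000)
            assert state.u == pytest.approx(-70.0, abs=1e-6)
            assert state.spikes == []

    def test_nonpositive_dt_rejected(self, lif_defaults):
        with pytest.raises(ValueError):
            step(NeuronState(u=-70.0), lif_defaults, 0.0, 0.0, 0.0)


class TestClosedForm:
    def test_identity_at_origin(self, lif_defaults):
        assert closed_form_potential(lif_defaults, -63.2, 123.0, 0.0) == -63.2

    def test_relaxation_limit(self, lif_defaults):
        assert closed_form_potential(lif_defaults, -60.0, 0.0, 1e6) == pytest.approx(-70.0)

    def test_point_value_at_10ms(self, lif_defaults):
        # E_L + R*I*(1 - e^-1) = -70 + 16*(1 - 1/e)
        expected = -70.0 + 16.0 * (1 - math.exp(-1.0))
        got = closed_form_potential(lif_defaults, -70.0, 400.0, 10.0)
        assert got == pytest.approx(expected, rel=1e-12)

    @given(u0=st.floats(-80.0, -56.0), I=st.floats(-200.0, 360.0),
           dt=st.floats(0.01, 1.0))
    def test_stepper_matches_closed_form_exactly(self, u0, I, dt):
        """The per-step exponential update reproduces the analytic
        subthreshold solution at every step boundary (any dt)."""
        params = LIFParams()
        n = 50
        traj, _ = _run_steps(params, u0, I, dt, n)
        t = np.arange(n + 1) * dt
        expected = closed_form_potential(params, u0, I, t)
        np.testing.assert_allclose(traj, expected, rtol=1e-9)


class TestRheobase:
    @pytest.mark.parametrize("params,expected", [
        (LIFParams(), 375.0),
        (LIFParams(V_th=-69.999999, E_L=-70.0), pytest.approx(0.0, abs=1e-4)),
        (LIFParams(C_m=500.0, tau_m=10.0), 750.0),
    ])
    def test_formula(self, params, expected):
        assert rheobase(params) == expected

    def test_exact_rheobase_never_fires(self, lif_defaults):
        """At I = 375 pA the fixed point equals the threshold; the strict
        approach from below means zero spikes even over a long run."""
        spikes, u = simulate_constant_current(lif_defaults, 375.0, 1000.0, 0.1)
        assert spikes.size == 0
        assert u < -55.0

    def test_just_above_rheobase_fires(self, lif_defaults):
        spikes, _ = simulate_constant_current(lif_defaults, 376.0, 200.0, 0.1)
        assert spikes.size >= 1
        # analytic time to threshold: tau * ln(15.04 / 0.04) ~ 59.29 ms
        assert spikes[0] == pytest.approx(time_to_first_spike(lif_defaults, 376.0),
                                          abs=0.1 + 1e-9)


class TestSpiking:
    @pytest.mark.parametrize("dt", [0.1, 0.01])
    def test_first_spike_time_matches_analytic_oracle(self, lif_defaults, dt):
        """For I=400 pA the closed-form time-to-threshold is
        tau*ln(16/1) = 27.726 ms; the stepped spike lands on the first step
        boundary at or after it."""
        t_star = 10.0 * math.log(16.0)
        spikes, _ = simulate_constant_current(lif_defaults, 400.0, 50.0, dt)
        assert spikes.size == 1  # the second spike would land at ~57.5 ms
        assert t_star <= spikes[0] <= t_star + dt + 1e-9

    def test_interspike_intervals_respect_refractory_period(self, lif_defaults):
        spikes, _ = simulate_constant_current(lif_defaults, 800.0, 200.0, 0.1)
        assert spikes.size > 3
        assert np.all(np.diff(spikes) >= lif_defaults.t_ref - 1e-12)

    def test_stronger_current_fires_earlier(self, lif_defaults):
        firsts = [simulate_constant_current(lif_defaults, I, 300.0, 0.1)[0][0]
                  for I in (380.0, 450.0, 700.0)]
        assert firsts[0] > firsts[1] > firsts[2]

    def test_simulation_is_deterministic(self, lif_defaults):
        a = simulate_constant_current(lif_defaults, 500.0, 150.0, 0.1)
        b = simulate_constant_current(lif_defaults, 500.0, 150.0, 0.1)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_reset_and_clamp_after_spike(self, lif_defaults):
        state = NeuronState(u=-55.05)
        state = step(state, lif_defaults, 2000.0, 0.1, 0.0)  # crosses
        assert state.spikes == [pytest.approx(0.1)]
        assert state.u == lif_defaults.V_reset
        # refractory: membrane stays clamped even under strong drive
        state = step(state, lif_defaults, 5000.0, 0.1, 0.1)
        assert state.u == lif_defaults.V_reset


class TestParamValidation:
    def test_derived_resistance(self, lif_defaults):
        assert lif_defaults.R == 40.0

    @pytest.mark.parametrize("kwargs", [
        {"tau_m": 0.0}, {"C_m": -1.0}, {"t_ref": -0.1},
        {"V_reset": -50.0}, {"E_L": -55.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LIFParams(**kwargs)

    def test_from_config_accepts_nest_style_names(self):
        p = LIFParams.from_config({"EL": -65.0, "Vth": -50.0, "Vreset": -65.0,
                                   "Cm": 200.0, "tau_m": 8.0, "Vm": -65.0})
        assert (p.E_L, p.V_th, p.V_reset, p.C_m, p.tau_m) == (
            -65.0, -50.0, -65.0, 200.0, 8.0)
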