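import math

import numpy as np
import pytest

from eibalance import neuron
from eibalance.neuron import (
    AMPA_KINETICS,
    DEFAULT_KINETICS,
    FAST_SPIKING,
    GABA_KINETICS,
    NMDA_KINETICS,
    REGULAR_SPIKING,
    ChannelKinetics,
    InvalidStateError,
    NeuronParameters,
    NeuronState,
    apply_spike_reset,
    impulse_response,
    initial_state,
    membrane_derivatives,
    rk4_step,
    simulate_constant_current,
    synaptic_current,
    update_channel,
)


class TestMembraneDerivatives:
    @pytest.mark.parametrize(
        "v,u,i_syn,exp_dv,exp_du",
        [
            (-65.0, -13.0, 0.0, -3.0, 0.0),   # resting polynomial evaluation
            (-65.0, -13.0, 3.0, 0.0, 0.0),    # equilibrium under 3 pA drive
        ],
    )
    def test_hand_evaluated_polynomial(self, v, u, i_syn, exp_dv, exp_du):
        dv, du = membrane_derivatives(v, u, REGULAR_SPIKING, i_syn)
        assert dv == pytest.approx(exp_dv)
        assert du == pytest.approx(exp_du)

    def test_linear_in_current(self, rng):
        for _ in range(20):
            v = rng.uniform(-80, 20)
            u = rng.uniform(-20, 5)
            k = rng.uniform(-10, 10)
            dv0, du0 = membrane_derivatives(v, u, FAST_SPIKING, 0.0)
            dvk, duk = membrane_derivatives(v, u, FAST_SPIKING, k)
            assert dvk - dv0 == pytest.approx(k)
            assert duk == du0

    def test_non_finite_state_rejected(self):
        with pytest.raises(InvalidStateError):
            membrane_derivatives(float("nan"), 0.0, REGULAR_SPIKING, 0.0)


class TestSpikeReset:
    def test_above_threshold_resets(self):
        v, u, spiked = apply_spike_reset(31.0, 0.0, REGULAR_SPIKING)
        assert (v, u, spiked) == (-65.0, 8.0, True)

    def test_below_threshold_unchanged(self):
        v, u, spiked = apply_spike_reset(29.999, 0.0, REGULAR_SPIKING)
        assert (v, u, spiked) == (29.999, 0.0, False)

    def test_threshold_inclusive(self):
        _, _, spiked = apply_spike_reset(30.0, 0.0, REGULAR_SPIKING)
        assert spiked


class TestSynapticCurrent:
    def test_gaba_reversal_at_minus_70(self):
        assert synaptic_current(-70.0, 0.0, 0.0, 1.0) == 0.0

    def test_nmda_block_vanishes_at_minus_80(self):
        assert synaptic_current(-80.0, 0.0, 1.0, 0.0) == 0.0

    def test_nmda_half_block_at_minus_20(self):
        # s = 1 at -20 mV: half the driving force of 20 mV
        assert synaptic_current(-20.0, 0.0, 1.0, 0.0) == pytest.approx(10.0)


class TestChannelKinetics:
    def test_stated_time_constants(self):
        assert (AMPA_KINETICS.tau1, AMPA_KINETICS.tau2) == (0.5, 2.4)
        assert (NMDA_KINETICS.tau1, NMDA_KINETICS.tau2) == (4.0, 40.0)
        assert (GABA_KINETICS.tau1, GABA_KINETICS.tau2) == (1.0, 7.0)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            ChannelKinetics(2.0, 1.0)

    def test_zero_state_is_fixed_point(self):
        g, x = 0.0, 0.0
        for _ in range(100):
            g, x = update_channel(g, x, AMPA_KINETICS, 0.05)
        assert (g, x) == (0.0, 0.0)

    def test_impulse_response_matches_closed_form(self):
        """Stepped kinetics track the analytic double exponential to < 1e-6
        relative error over 50 ms at dt = 0.05 ms."""
        dt = 0.05
        n = int(50 / dt)
        for kin in DEFAULT_KINETICS:
            g, x = update_channel(0.0, 0.0, kin, dt, arrival_weight=1.0)
            times = []
            values = []
            for step in range(1, n):
                times.append(step * dt)
                values.append(g)
                g, x = update_channel(g, x, kin, dt)
            expected = impulse_response(kin, np.array(times))
            peak = expected.max()
            assert np.max(np.abs(np.array(values) - expected)) / peak < 1e-6

    def test_ampa_peak_time(self):
        assert AMPA_KINETICS.peak_time == pytest.approx(0.9907, abs=1e-4)
        # unit-weight impulse is normalized to unit peak conductance
        t = np.linspace(0, 10, 10001)
        assert impulse_response(AMPA_KINETICS, t).max() == pytest.approx(1.0, abs=1e-6)

    def test_response_linear_in_weight(self):
        t = np.linspace(0, 20, 200)
        assert np.allclose(
            impulse_response(AMPA_KINETICS, t, w=2.0),
            2.0 * impulse_response(AMPA_KINETICS, t),
        )


class TestRK4:
    def test_resting_state_stays_subthreshold(self):
        """Zero input from the standard initial state: the cell relaxes to the
        stable fixed point near -70 mV and never spikes over 1 s."""
        v_trace, spikes = simulate_constant_current(REGULAR_SPIKING, 0.0, 1000.0)
        assert spikes.size == 0
        assert np.all((v_trace > -75.0) & (v_trace < -60.0))
        assert v_trace[-1] == pytest.approx(-70.0, abs=0.5)

    def test_rs_adapts_and_fs_fires_faster(self):
        """Constant 10 pA: the RS cell shows non-decreasing ISIs (adaptation)
        and the FS cell a higher rate, matching a fine-step reference."""
        for dt in (0.05, 0.001):  # coarse run and reference agree qualitatively
            _, rs_spikes = simulate_constant_current(REGULAR_SPIKING, 10.0, 800.0, dt=dt)
            _, fs_spikes = simulate_constant_current(FAST_SPIKING, 10.0, 800.0, dt=dt)
            assert rs_spikes.size >= 5
            isis = np.diff(rs_spikes[:6])
            assert np.all(np.diff(isis) > -0.1)  # non-decreasing (adaptation)
            assert fs_spikes.size > rs_spikes.size

    def test_convergence_order(self):
        """Global error on a 100 ms subthreshold trajectory scales as O(dt^4)."""
        ref, _ = simulate_constant_current(REGULAR_SPIKING, 1.0, 100.0, dt=0.001)
        errors = []
        for dt in (0.1, 0.05, 0.025):
            v, _ = simulate_constant_current(REGULAR_SPIKING, 1.0, 100.0, dt=dt)
            stride = int(round(dt / 0.001))
            errors.append(np.max(np.abs(v - ref[::stride])))
        slopes = np.diff(np.log(errors)) / np.diff(np.log([0.1, 0.05, 0.025]))
        assert np.all(slopes > 3.5)

    def test_rk4_step_reset_contract(self):
        # just below threshold with a steep upstroke: crosses within one step
        state = NeuronState(v=29.9, u=0.0)
        out, spiked = rk4_step(state, REGULAR_SPIKING, dt=0.05)
        assert spiked
        assert out.v == REGULAR_SPIKING.c
        assert out.u == pytest.approx(REGULAR_SPIKING.d, abs=0.5)

    def test_initial_state_convention(self):
        s = initial_state(FAST_SPIKING)
        assert s.v == -65.0
        assert s.u == pytest.approx(FAST_SPIKING.b * -65.0)
        assert np.all(s.g == 0.0) and np.all(s.x == 0.0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        NeuronParameters(a=-0.1, b=0.2, c=-65.0, d=8.0)
    with pytest.raises(ValueError):
        NeuronParameters(a=0.02, b=0.2, c=40.0, d=8.0)
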