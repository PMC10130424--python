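import math

import numpy as np
import pytest

from eibalance.stdp import (
    PlasticityParameters,
    SpikeTraces,
    decay_traces,
    on_postsynaptic_spike,
    on_presynaptic_arrival,
    pair_ltd,
    pair_ltp,
    run_event_driven,
)

from .oracles import poisson_trains_with_refractory, triplet_stdp_dense_grid

PARAMS = PlasticityParameters()


class TestTraces:
    def test_exponential_decay_closed_form(self):
        tr = decay_traces(SpikeTraces(r1=1.0), 16.8, PARAMS)
        assert tr.r1 == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_zero_traces_fixed_point(self):
        tr = decay_traces(SpikeTraces(), 100.0, PARAMS)
        assert (tr.r1, tr.r2, tr.o1, tr.o2) == (0.0, 0.0, 0.0, 0.0)

    def test_spike_increments_by_one(self):
        _, tr = on_presynaptic_arrival(0.02, SpikeTraces(r1=0.5, r2=0.25), PARAMS)
        assert (tr.r1, tr.r2) == (1.5, 1.25)
        _, tr = on_postsynaptic_spike(0.02, SpikeTraces(o1=0.3, o2=0.1), PARAMS)
        assert (tr.o1, tr.o2) == (1.3, 1.1)

    def test_negative_traces_rejected(self):
        with pytest.raises(ValueError):
            SpikeTraces(r1=-0.1)


class TestSingleEvents:
    def test_no_post_history_no_depression(self):
        w, _ = on_presynaptic_arrival(0.02, SpikeTraces(o1=0.0), PARAMS)
        assert w == 0.02

    def test_pair_depression_closed_form(self):
        """Post spike 10 ms before a pre arrival gives the exponential
        pair-window depression -A2m * exp(-10/33.7)."""
        w = run_event_driven([10.0], [0.0], 0.02, PARAMS)
        expected = 0.02 - pair_ltd(10.0, PARAMS)
        assert w == pytest.approx(expected, rel=1e-12)
        assert pair_ltd(10.0, PARAMS) == pytest.approx(7e-4 * math.exp(-10 / 33.7), rel=1e-12)

    def test_pair_potentiation_closed_form(self):
        """Pre arrival 10 ms before a post spike: only the pair term A2p
        contributes (o2 history empty)."""
        w = run_event_driven([0.0], [10.0], 0.02, PARAMS)
        assert w - 0.02 == pytest.approx(pair_ltp(10.0, PARAMS), rel=1e-9)

    def test_weight_clipped_at_lower_bound(self):
        w = run_event_driven([10.0], [9.0], 1e-5, PARAMS)
        assert w == 0.0

    def test_weight_clipped_at_upper_bound(self):
        strong = PlasticityParameters(a2_plus=0.1)
        w = run_event_driven([0.0], [5.0], 0.039, strong)
        assert w == strong.w_max

    def test_r1_gate_blocks_potentiation(self):
        w, _ = on_postsynaptic_spike(0.02, SpikeTraces(r1=0.0, o2=5.0), PARAMS)
        assert w == 0.02


class TestTripletStructure:
    def test_triplet_term_grows_second_potentiation(self):
        """pre-post-pre-post at 10 ms spacing: the second potentiation exceeds
        the first because o2 > 0 at the second post spike."""
        _, hist = run_event_driven(
            [0.0, 20.0], [10.0, 30.0], 0.02, PARAMS, record=True
        )
        dws = []
        w_prev = 0.02
        for t, kind, w in hist:
            if kind == "post":
                dws.append(w - w_prev)
            w_prev = w
        assert len(dws) == 2
        assert dws[1] > dws[0] > 0

    def test_pair_reduction_matches_closed_form(self):
        """With the triplet amplitudes zeroed the rule is exactly pair STDP."""
        params = PlasticityParameters(a3_plus=0.0, a3_minus=0.0, w_max=10.0)
        rng = np.random.default_rng(7)
        pre = np.sort(rng.uniform(0, 500, 12))
        post = pre + 10.0  # every pre leads its post by 10 ms
        # start far from both bounds so no update clips
        w = run_event_driven(pre, post, 0.5, params)
        # closed form: each post potentiates by the sum over prior pre arrivals,
        # each pre depresses by the sum over prior posts
        expected = 0.5
        for i, tp in enumerate(post):
            expected += sum(params.a2_plus * math.exp(-(tp - ta) / params.tau_plus)
                            for ta in pre if ta <= tp)
            # pre arrival i+1 (if any) depressed by all earlier posts
        for ta in pre:
            expected -= sum(params.a2_minus * math.exp(-(ta - tq) / params.tau_minus)
                            for tq in post if tq < ta)
        assert w == pytest.approx(expected, rel=1e-9)

    def test_frequency_dependence(self):
        """At fixed +10 ms lag, 60 pairings potentiate more at 40 Hz than at
        1 Hz (the triplet signature; weight bounds widened to avoid clipping)."""
        wide = PlasticityParameters(w_max=10.0)
        results = {}
        for f in (1.0, 40.0):
            period = 1000.0 / f
            pre = np.arange(60) * period
            post = pre + 10.0
            results[f] = run_event_driven(pre, post, 1.0, wide) - 1.0
        assert results[40.0] > results[1.0]


class TestDenseGridOracle:
    def test_event_driven_matches_dense_integration(self):
        """Event-driven weight updates agree with brute-force dense-grid trace
        integration to relative error < 1e-6 on random spike trains."""
        rng = np.random.default_rng(123)
        pre_trains = poisson_trains_with_refractory(rng, 20, 5.0, 1000.0)
        post_trains = poisson_trains_with_refractory(rng, 20, 5.0, 1000.0)
        for pre, post in zip(pre_trains, post_trains):
            if pre.size == 0 or post.size == 0:
                continue
            w_event = run_event_driven(pre, post, 0.02, PARAMS)
            w_dense = triplet_stdp_dense_grid(pre, post, 0.02, PARAMS, grid_dt=0.001)
            assert w_dense == pytest.approx(w_event, rel=1e-6, abs=1e-12)

    def test_window_gating(self):
        """Updates outside the plasticity window leave the weight untouched
        while traces keep evolving (oracle agreement with a window)."""
        rng = np.random.default_rng(5)
        pre = poisson_trains_with_refractory(rng, 1, 8.0, 600.0)[0]
        post = poisson_trains_with_refractory(rng, 1, 8.0, 600.0)[0]
        window = (100.0, 400.0)
        w_event = run_event_driven(pre, post, 0.02, PARAMS, window=window)
        w_dense = triplet_stdp_dense_grid(pre, post, 0.02, PARAMS, window=window)
        assert w_dense == pytest.approx(w_event, rel=1e-6, abs=1e-12)
        # all-outside window: no change at all
        assert run_event_driven([450.0], [460.0], 0.02, PARAMS, window=(0, 100)) == 0.02


def test_parameter_values_and_validation():
    p = PARAMS
    assert (p.a2_plus, p.a2_minus, p.a3_plus, p.a3_minus) == (5e-11, 7e-4, 6.2e-4, 2.3e-5)
    assert (p.tau_plus, p.tau_minus, p.tau_x, p.tau_y) == (16.8, 33.7, 101.0, 125.0)
    assert (p.w_min, p.w_max) == (0.0, 0.04)
    with pytest.raises(ValueError):
        PlasticityParameters(tau_plus=-1.0)
    with pytest.raises(ValueError):
        PlasticityParameters(w_min=0.05)
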