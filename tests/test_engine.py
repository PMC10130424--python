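import numpy as np
import pytest

from eibalance.engine import (
    LAPSeries,
    Recording,
    SimulationSchedule,
    compute_firing_rates,
    compute_lap,
    downsample_lap,
    run_simulation,
)
from eibalance.network import ConnectionTable, GroupSpec, build_network, two_group_topology
from eibalance.neuron import DEFAULT_KINETICS, NeuronState, initial_state, rk4_step, REGULAR_SPIKING
from eibalance.stdp import PlasticityParameters, run_event_driven
from eibalance.stimulus import InputEvents


def make_pair_table(weight=0.03, delay=40, inhibitory=False, plastic=None):
    """Two RS neurons in one group with a single synapse 0 -> 1."""
    if plastic is None:
        plastic = not inhibitory
    return ConnectionTable(
        pre=np.array([0], dtype=np.int32),
        post=np.array([1], dtype=np.int32),
        weight=np.array([weight]),
        delay_steps=np.array([delay], dtype=np.int32),
        inhibitory=np.array([inhibitory]),
        plastic=np.array([plastic]),
        group_of=np.zeros(2, dtype=np.int32),
        is_excitatory=np.ones(2, dtype=bool),
    )


def driven_events(target, times_ms, weight=2.0, dt=0.05):
    steps = np.array([int(round(t / dt)) for t in times_ms], dtype=np.int64)
    return InputEvents(
        steps=steps,
        targets=np.full(steps.size, target, dtype=np.int32),
        weights=np.full(steps.size, weight),
    )


@pytest.fixture(scope="module")
def short_schedule():
    return SimulationSchedule.scaled(stdp_duration_s=0.5, warmup_s=0.1,
                                     analysis_s=0.2, input_s=0.2)


class TestSchedule:
    def test_paper_layout(self):
        s = SimulationSchedule.paper()
        assert s.total_s == 1520.0
        assert s.stdp_window_s == (5.0, 1505.0)
        assert s.complexity_window_s == (1510.0, 1515.0)
        assert s.input_window_s == (1515.0, 1520.0)
        assert s.dt_ms == 0.05
        assert s.n_steps == 30_400_000

    def test_windows_validated(self):
        with pytest.raises(ValueError):
            SimulationSchedule(total_s=10.0, stdp_window_s=(5.0, 15.0))


class TestEngineContracts:
    def test_silent_network_stays_silent(self, short_schedule):
        table = make_pair_table(weight=0.0)
        rec = run_simulation(table, short_schedule)
        assert rec.spike_steps.size == 0
        # relaxes from the -65 mV initial state to the -70 mV fixed point
        # (with a small undershoot while u catches up)
        assert np.all((rec.lap > -73.0) & (rec.lap < -64.0))
        assert abs(rec.lap[-1, 0] + 70.0) < 0.5

    def test_delay_line_shift_contract(self, short_schedule):
        """Shifting a synapse's delay by k steps shifts the postsynaptic spike
        by exactly k steps (delivery = spike step + delay_steps)."""
        spikes = {}
        for delay in (40, 60):
            table = make_pair_table(weight=5.0, delay=delay)
            rec = run_simulation(
                table, short_schedule, driven_events(0, [200.0]),
                plastic_enabled=False,
            )
            post = rec.spike_steps[rec.spike_ids == 1]
            assert post.size >= 1
            spikes[delay] = post[0]
        assert spikes[60] - spikes[40] == 20

    def test_zero_weight_matches_isolated_integrator(self, short_schedule):
        """With all weights zero, every neuron follows the single-neuron
        reference integrator driven by the same input events."""
        table = make_pair_table(weight=0.0)
        times = [50.0, 120.0, 121.5]
        rec = run_simulation(
            table, short_schedule, driven_events(0, times, weight=2.0),
            record_v_ids=np.array([0]),
        )
        dt = short_schedule.dt_ms
        state = initial_state(REGULAR_SPIKING)
        arrival_steps = {int(round(t / dt)) for t in times}
        ref = np.empty(short_schedule.n_steps)
        for step in range(short_schedule.n_steps):
            arr = np.zeros(3)
            if step in arrival_steps:
                arr[0] += 2.0
                arr[1] += 2.0
            pre = state
            nxt, spiked = rk4_step(state, REGULAR_SPIKING, dt=dt, arrivals=arr)
            ref[step] = 30.0 if spiked else nxt.v
            state = nxt
        assert np.max(np.abs(rec.v_trace[:, 0] - ref)) < 1e-9

    def test_determinism_bit_reproducible(self, short_schedule):
        specs = [GroupSpec(100, 25), GroupSpec(100, 25)]
        results = []
        for _ in range(2):
            table = build_network(two_group_topology(), specs, seed=77)
            rec = run_simulation(table, short_schedule, driven_events(0, [50.0, 80.0]))
            results.append(rec)
        a, b = results
        assert np.array_equal(a.spike_steps, b.spike_steps)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        assert np.array_equal(a.final_weights, b.final_weights)
        assert np.array_equal(a.lap, b.lap)

    def test_engine_stdp_matches_event_driven_reference(self, short_schedule):
        """A driven pre/post pair: the engine's final weight equals the scalar
        event-driven rule replayed on the recorded spike times."""
        delay = 40
        w0 = 0.02
        table = make_pair_table(weight=w0, delay=delay)
        # drive both neurons directly; pre leads post by ~3 ms repeatedly
        pre_times = list(np.arange(150.0, 900.0, 50.0))
        post_times = [t + 3.0 for t in pre_times]
        events = InputEvents(
            steps=np.array(
                [int(round(t / 0.05)) for t in pre_times]
                + [int(round(t / 0.05)) for t in post_times],
                dtype=np.int64,
            ),
            targets=np.array([0] * len(pre_times) + [1] * len(post_times), dtype=np.int32),
            weights=np.full(2 * len(pre_times), 3.0),
        ).sorted()
        rec = run_simulation(table, short_schedule, events)
        dt = short_schedule.dt_ms
        pre_spk = rec.spike_steps[rec.spike_ids == 0] * dt
        post_spk = rec.spike_steps[rec.spike_ids == 1] * dt
        stdp_ms = (short_schedule.stdp_window_s[0] * 1e3,
                   short_schedule.stdp_window_s[1] * 1e3)
        w_ref = run_event_driven(
            pre_spk + delay * dt, post_spk, w0, PlasticityParameters(), window=stdp_ms
        )
        assert rec.final_weights[0] == pytest.approx(w_ref, rel=1e-9)

    def test_plasticity_disabled_freezes_weights(self, short_schedule):
        specs = [GroupSpec(100, 25), GroupSpec(100, 25)]
        table = build_network(two_group_topology(), specs, seed=3)
        rec = run_simulation(table, short_schedule, driven_events(0, [50.0]),
                             plastic_enabled=False)
        assert np.array_equal(rec.initial_weights, rec.final_weights)


class TestLAP:
    def test_constant_field(self):
        v = np.full((10, 5), -65.0)
        assert np.allclose(compute_lap(v), -65.0)

    def test_mean_of_two_halves(self):
        v = np.column_stack([np.full(4, -70.0), np.full(4, -60.0)])
        assert np.allclose(compute_lap(v), -65.0)

    def test_clamp_at_threshold(self):
        v = np.array([[45.0, -65.0]])
        assert compute_lap(v)[0] == pytest.approx((30.0 - 65.0) / 2)

    def test_engine_lap_clamped(self, short_schedule):
        table = make_pair_table(weight=0.0)
        rec = run_simulation(table, short_schedule, driven_events(0, [100.0], weight=5.0))
        assert rec.spike_steps.size >= 1
        assert rec.lap.max() <= 30.0


class TestDownsample:
    def test_constant_series(self):
        out = downsample_lap(np.full(100, -64.0), 0.05, 1.0)
        assert np.allclose(out, -64.0)
        assert out.shape == (5,)

    def test_hand_block_average(self):
        x = np.arange(40, dtype=float)
        out = downsample_lap(x, 0.05, 1.0)
        assert np.allclose(out, [np.mean(np.arange(20)), np.mean(np.arange(20, 40))])

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            downsample_lap(np.zeros(100), 0.05, 0.13)

    def test_lapseries_metadata_propagates(self):
        s = LAPSeries(values=np.zeros(200), interval_ms=0.05, group=1, t_start_s=2.0)
        out = downsample_lap(s, target_interval_ms=1.0)
        assert isinstance(out, LAPSeries)
        assert out.interval_ms == 1.0 and out.group == 1
        assert out.values.shape == (10,)


class TestFiringRates:
    def test_silent_raster(self, short_schedule):
        table = make_pair_table(weight=0.0)
        rec = run_simulation(table, short_schedule)
        rates = compute_firing_rates(rec, short_schedule.complexity_window_s)
        assert rates[(0, "excitatory")] == 0.0

    def test_counted_rate_and_additivity(self, short_schedule):
        """Handcrafted raster: 5 spikes of one of two neurons over 0.2 s gives
        5/2/0.2 Hz, and rates over equal half-windows average to the full rate."""
        table = make_pair_table(weight=0.0)
        t0_step, t1_step = short_schedule.window_steps(short_schedule.complexity_window_s)
        steps = np.linspace(t0_step + 100, t1_step - 100, 5).astype(np.int64)
        rec = Recording(
            spike_steps=steps,
            spike_ids=np.zeros(5, dtype=np.int64),
            lap=np.zeros((short_schedule.n_steps, 1)),
            initial_weights=table.weight,
            final_weights=table.weight,
            schedule=short_schedule,
            table=table,
        )
        w0, w1 = short_schedule.complexity_window_s
        rates = compute_firing_rates(rec, (w0, w1))
        assert rates[(0, "excitatory")] == pytest.approx(5 / 2 / 0.2)
        mid = (w0 + w1) / 2
        r_a = compute_firing_rates(rec, (w0, mid))[(0, "excitatory")]
        r_b = compute_firing_rates(rec, (mid, w1))[(0, "excitatory")]
        assert (r_a + r_b) / 2 == pytest.approx(rates[(0, "excitatory")])

    def test_empty_window_rejected(self, short_schedule):
        table = make_pair_table()
        rec = run_simulation(table, short_schedule)
        with pytest.raises(ValueError):
            compute_firing_rates(rec, (0.5, 0.5))


def test_recording_hdf5_roundtrip(short_schedule, tmp_path):
    table = make_pair_table(weight=0.0)
    rec = run_simulation(table, short_schedule, driven_events(0, [100.0], weight=5.0))
    path = tmp_path / "rec.h5"
    rec.save_hdf5(path)
    import h5py

    with h5py.File(path) as f:
        assert np.array_equal(f["spike_steps"][...], rec.spike_steps)
        assert f["lap"].shape == rec.lap.shape
        assert f.attrs["dt_ms"] == 0.05
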