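"""Time-stepped network simulation engine.

Orchestrates the full loop at dt = 0.05 ms: deliver delayed spikes into the
channel gates, advance every neuron one RK4 step (channel cascades propagated
with their exact exponential solution), detect and reset spikes, enqueue
outgoing deliveries through per-synapse delay lines, and apply the triplet
STDP rule event-wise while the plasticity window is active.  Per-group local
average potentials (LAP: the mean membrane potential of a group's excitatory
neurons, clamped at the 30 mV threshold) are recorded every step.

Timing conventions.  A spike detected while integrating step s is stamped at
step s+1 (time (s+1) dt); its synaptic arrivals are processed at the start of
step (s+1) + delay_steps, so arrival minus spike equals the delay exactly.
External input events at step s enter the conductance gates at the start of
that step.  Everything is pure arithmetic on pre-generated event arrays, so a
fixed seed reproduces rasters and weights bit-for-bit.

The hot loop is compiled with numba; excitatory deliveries travel through a
pooled linked-list ring buffer (delays are bounded by 10 ms = 200 steps) and
static inhibitory deliveries through a dense circular accumulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import ConnectionTable
from .neuron import (
    DEFAULT_KINETICS,
    FAST_SPIKING,
    REGULAR_SPIKING,
    NumericalInstabilityError,
    channel_propagator,
)
from .stdp import PlasticityParameters
from .stimulus import InputEvents

STATUS_OK = 0
STATUS_DIVERGED = 1
STATUS_SPIKE_OVERFLOW = 2
STATUS_POOL_OVERFLOW = 3


@dataclass(frozen=True)
class SimulationSchedule:
    """Phase layout of a run (all times in seconds; dt in ms).

    The production layout is 1,520 s total with plasticity active on
    [5, 1505), the complexity-analysis window on [1510, 1515) and the
    external-input window on [1515, 1520).  ``scaled`` builds a compressed
    desk-scale layout with the same phase ordering.
    """

    dt_ms: float = 0.05
    total_s: float = 1520.0
    stdp_window_s: tuple[float, float] = (5.0, 1505.0)
    complexity_window_s: tuple[float, float] = (1510.0, 1515.0)
    input_window_s: tuple[float, float] = (1515.0, 1520.0)
    scale_note: str = "production"

    def __post_init__(self) -> None:
        for w in (self.stdp_window_s, self.complexity_window_s, self.input_window_s):
            if not (0.0 <= w[0] < w[1] <= self.total_s):
                raise ValueError(f"window {w} outside the run duration")

    @classmethod
    def paper(cls) -> "SimulationSchedule":
        return cls()

    @classmethod
    def scaled(
        cls,
        stdp_duration_s: float = 60.0,
        warmup_s: float = 2.0,
        analysis_s: float = 5.0,
        input_s: float = 5.0,
    ) -> "SimulationSchedule":
        t_stdp_end = warmup_s + stdp_duration_s
        return cls(
            total_s=t_stdp_end + analysis_s + input_s,
            stdp_window_s=(warmup_s, t_stdp_end),
            complexity_window_s=(t_stdp_end, t_stdp_end + analysis_s),
            input_window_s=(t_stdp_end + analysis_s, t_stdp_end + analysis_s + input_s),
            scale_note="desk-scale",
        )

    @property
    def n_steps(self) -> int:
        return int(round(self.total_s * 1e3 / self.dt_ms))

    def window_steps(self, window_s: tuple[float, float]) -> tuple[int, int]:
        return (
            int(round(window_s[0] * 1e3 / self.dt_ms)),
            int(round(window_s[1] * 1e3 / self.dt_ms)),
        )


@dataclass
class LAPSeries:
    """A local-average-potential time series with sampling metadata."""

    values: np.ndarray
    interval_ms: float
    group: int
    t_start_s: float = 0.0


@dataclass
class Recording:
    """Everything captured from one run."""

    spike_steps: np.ndarray
    spike_ids: np.ndarray
    lap: np.ndarray  # (n_steps, n_groups) at dt resolution
    initial_weights: np.ndarray
    final_weights: np.ndarray
    schedule: SimulationSchedule
    table: ConnectionTable
    v_trace: np.ndarray | None = None
    v_trace_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def lap_series(self, group: int, window_s: tuple[float, float] | None = None) -> LAPSeries:
        s0, s1 = (0, self.lap.shape[0]) if window_s is None else self.schedule.window_steps(window_s)
        return LAPSeries(
            values=self.lap[s0:s1, group].copy(),
            interval_ms=self.schedule.dt_ms,
            group=group,
            t_start_s=s0 * self.schedule.dt_ms * 1e-3,
        )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("spike_steps", data=self.spike_steps)
            f.create_dataset("spike_ids", data=self.spike_ids)
            f.create_dataset("lap", data=self.lap)
            f.create_dataset("initial_weights", data=self.initial_weights)
            f.create_dataset("final_weights", data=self.final_weights)
            f.attrs["dt_ms"] = self.schedule.dt_ms
            f.attrs["total_s"] = self.schedule.total_s
            for k, v in self.metadata.items():
                if isinstance(v, (int, float, str)):
                    f.attrs[k] = v


@njit(cache=True)
def _i_syn(v, ga, gn, gg):  # pragma: no cover - numba inline
    s = ((v + 80.0) / 60.0) ** 2
    return ga * (0.0 - v) + gn * s / (1.0 + s) * (0.0 - v) + gg * (-70.0 - v)


@njit(cache=True)
def _run_kernel(  # pragma: no cover - exercised through run_simulation
    n_steps, dt,
    a_arr, b_arr, c_arr, d_arr,
    v, u, g, x,
    e1f, e2f, e1h, e2h, dco,
    syn_ptr, syn_post, syn_w, syn_delay, syn_inhib, syn_plastic,
    in_ptr, in_idx,
    ev_step, ev_target, ev_weight,
    a2p, a2m, a3p, a3m, tp, tm, tx, ty, eps, wmin, wmax, plastic_on,
    stdp_start_ms, stdp_end_ms,
    r1, r2, last_arr, o1, o2, last_post,
    q_head, q_syn, q_next, q_free,
    buf_i,
    grp_exc_ptr, grp_exc_ids,
    lap_out,
    spike_steps, spike_ids,
    v_clamp,
    vrec_ids, vrec_out,
):
    N = v.shape[0]
    G = grp_exc_ptr.shape[0] - 1
    D = buf_i.shape[0]
    P = q_syn.shape[0]
    free_top = P
    for i in range(P):
        q_free[i] = i
    ev_ptr = 0
    n_ev = ev_step.shape[0]
    n_spk = 0
    cap = spike_steps.shape[0]

    for step in range(n_steps):
        t_now = step * dt
        row = step % D
        dep_active = plastic_on and (t_now >= stdp_start_ms) and (t_now < stdp_end_ms)

        # external/background input events scheduled for this step
        while ev_ptr < n_ev and ev_step[ev_ptr] == step:
            tgt = ev_target[ev_ptr]
            wv = ev_weight[ev_ptr]
            x[tgt, 0] += wv
            x[tgt, 1] += wv
            ev_ptr += 1

        # static inhibitory deliveries
        for i in range(N):
            bi = buf_i[row, i]
            if bi != 0.0:
                x[i, 2] += bi
                buf_i[row, i] = 0.0

        # excitatory (plastic) synapse arrivals: depression, delivery, r-trace bumps
        node = q_head[row]
        q_head[row] = -1
        while node != -1:
            s_idx = q_syn[node]
            nxt = q_next[node]
            q_free[free_top] = node
            free_top += 1
            post = syn_post[s_idx]
            wv = syn_w[s_idx]
            if dep_active:
                o1v = o1[post] * math.exp(-(t_now - last_post[post]) / tm)
                el = t_now - eps - last_arr[s_idx]
                if el < 0.0:
                    el = 0.0
                r2v = r2[s_idx] * math.exp(-el / tx)
                wv = wv - o1v * (a2m + a3m * r2v)
                if wv < wmin:
                    wv = wmin
                syn_w[s_idx] = wv
            x[post, 0] += wv
            x[post, 1] += wv
            elp = t_now - last_arr[s_idx]
            r1[s_idx] = r1[s_idx] * math.exp(-elp / tp) + 1.0
            r2[s_idx] = r2[s_idx] * math.exp(-elp / tx) + 1.0
            last_arr[s_idx] = t_now
            node = nxt

        # advance all neurons one step
        t_spike = (step + 1) * dt
        pot_active = plastic_on and (t_spike >= stdp_start_ms) and (t_spike < stdp_end_ms)
        for i in range(N):
            g0a = g[i, 0]; g0n = g[i, 1]; g0g = g[i, 2]
            x0a = x[i, 0]; x0n = x[i, 1]; x0g = x[i, 2]
            gha = g0a * e1h[0] + dco[0] * x0a * (e2h[0] - e1h[0])
            ghn = g0n * e1h[1] + dco[1] * x0n * (e2h[1] - e1h[1])
            ghg = g0g * e1h[2] + dco[2] * x0g * (e2h[2] - e1h[2])
            g1a = g0a * e1f[0] + dco[0] * x0a * (e2f[0] - e1f[0])
            g1n = g0n * e1f[1] + dco[1] * x0n * (e2f[1] - e1f[1])
            g1g = g0g * e1f[2] + dco[2] * x0g * (e2f[2] - e1f[2])

            vv = v[i]; uu = u[i]
            ai = a_arr[i]; bi_ = b_arr[i]
            k1v = 0.04 * vv * vv + 5.0 * vv + 140.0 - uu + _i_syn(vv, g0a, g0n, g0g)
            k1u = ai * (bi_ * vv - uu)
            v1 = vv + 0.5 * dt * k1v; u1 = uu + 0.5 * dt * k1u
            k2v = 0.04 * v1 * v1 + 5.0 * v1 + 140.0 - u1 + _i_syn(v1, gha, ghn, ghg)
            k2u = ai * (bi_ * v1 - u1)
            v2 = vv + 0.5 * dt * k2v; u2 = uu + 0.5 * dt * k2u
            k3v = 0.04 * v2 * v2 + 5.0 * v2 + 140.0 - u2 + _i_syn(v2, gha, ghn, ghg)
            k3u = ai * (bi_ * v2 - u2)
            v3 = vv + dt * k3v; u3 = uu + dt * k3u
            k4v = 0.04 * v3 * v3 + 5.0 * v3 + 140.0 - u3 + _i_syn(v3, g1a, g1n, g1g)
            k4u = ai * (bi_ * v3 - u3)
            vn = vv + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            un = uu + dt / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)

            g[i, 0] = g1a; g[i, 1] = g1n; g[i, 2] = g1g
            x[i, 0] = x0a * e2f[0]; x[i, 1] = x0n * e2f[1]; x[i, 2] = x0g * e2f[2]

            if vn >= 30.0:
                if n_spk >= cap:
                    return STATUS_SPIKE_OVERFLOW, n_spk
                spike_steps[n_spk] = step + 1
                spike_ids[n_spk] = i
                n_spk += 1
                v_clamp[i] = 30.0
                if pot_active and in_ptr[i + 1] > in_ptr[i]:
                    elo = t_spike - eps - last_post[i]
                    if elo < 0.0:
                        elo = 0.0
                    o2v = o2[i] * math.exp(-elo / ty)
                    for p_ in range(in_ptr[i], in_ptr[i + 1]):
                        sj = in_idx[p_]
                        r1v = r1[sj] * math.exp(-(t_spike - last_arr[sj]) / tp)
                        wv2 = syn_w[sj] + r1v * (a2p + a3p * o2v)
                        if wv2 > wmax:
                            wv2 = wmax
                        syn_w[sj] = wv2
                elo2 = t_spike - last_post[i]
                o1[i] = o1[i] * math.exp(-elo2 / tm) + 1.0
                o2[i] = o2[i] * math.exp(-elo2 / ty) + 1.0
                last_post[i] = t_spike
                for sp in range(syn_ptr[i], syn_ptr[i + 1]):
                    dstep = step + 1 + syn_delay[sp]
                    slot = dstep % D
                    if syn_inhib[sp]:
                        buf_i[slot, syn_post[sp]] += syn_w[sp]
                    else:
                        if free_top == 0:
                            return STATUS_POOL_OVERFLOW, n_spk
                        free_top -= 1
                        nd = q_free[free_top]
                        q_syn[nd] = sp
                        q_next[nd] = q_head[slot]
                        q_head[slot] = nd
                vn = c_arr[i]
                un = un + d_arr[i]
            else:
                if vn > 1000.0:
                    return STATUS_DIVERGED, n_spk
                v_clamp[i] = vn
            v[i] = vn
            u[i] = un

        # per-group LAP over excitatory members (clamped pre-reset potentials)
        for gi in range(G):
            acc = 0.0
            lo = grp_exc_ptr[gi]
            hi = grp_exc_ptr[gi + 1]
            for p_ in range(lo, hi):
                acc += v_clamp[grp_exc_ids[p_]]
            lap_out[step, gi] = acc / (hi - lo)

        for ri in range(vrec_ids.shape[0]):
            vrec_out[step, ri] = v_clamp[vrec_ids[ri]]

    return STATUS_OK, n_spk


def _csr_by_pre(table: ConnectionTable):
    order = np.argsort(table.pre, kind="stable")
    pre_sorted = table.pre[order]
    ptr = np.zeros(table.n_neurons + 1, dtype=np.int64)
    np.add.at(ptr, pre_sorted + 1, 1)
    np.cumsum(ptr, out=ptr)
    return order, ptr


def run_simulation(
    table: ConnectionTable,
    schedule: SimulationSchedule,
    events: InputEvents | None = None,
    plasticity: PlasticityParameters | None = None,
    plastic_enabled: bool = True,
    kinetics=DEFAULT_KINETICS,
    record_v_ids: np.ndarray | None = None,
    max_mean_rate_hz: float = 250.0,
    metadata: dict | None = None,
) -> Recording:
    """Run one full simulation and return its :class:`Recording`.

    ``events`` supplies all external/background input spikes (step-sorted).
    ``plastic_enabled=False`` freezes every weight (the no-plasticity
    control); traces still evolve.  Raises on numerical divergence.
    """
    plasticity = plasticity or PlasticityParameters()
    dt = schedule.dt_ms
    n_steps = schedule.n_steps
    n = table.n_neurons

    order, syn_ptr = _csr_by_pre(table)
    syn_post = table.post[order].astype(np.int64)
    syn_w = table.weight[order].astype(np.float64).copy()
    syn_delay = table.delay_steps[order].astype(np.int64)
    syn_inhib = table.inhibitory[order].copy()
    syn_plastic = table.plastic[order].copy()
    initial_weights = syn_w.copy()

    # incoming plastic synapses grouped by postsynaptic neuron
    plastic_idx = np.flatnonzero(syn_plastic)
    by_post = np.argsort(syn_post[plastic_idx], kind="stable")
    in_idx = plastic_idx[by_post].astype(np.int64)
    in_ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(in_ptr, syn_post[in_idx] + 1, 1)
    np.cumsum(in_ptr, out=in_ptr)

    # per-neuron Izhikevich constants
    a_arr = np.where(table.is_excitatory, REGULAR_SPIKING.a, FAST_SPIKING.a)
    b_arr = np.where(table.is_excitatory, REGULAR_SPIKING.b, FAST_SPIKING.b)
    c_arr = np.where(table.is_excitatory, REGULAR_SPIKING.c, FAST_SPIKING.c)
    d_arr = np.where(table.is_excitatory, REGULAR_SPIKING.d, FAST_SPIKING.d)

    v = np.full(n, -65.0)
    u = b_arr * v
    g = np.zeros((n, 3))
    x = np.zeros((n, 3))

    e1f = np.empty(3); e2f = np.empty(3); e1h = np.empty(3); e2h = np.empty(3); dco = np.empty(3)
    for ch, kin in enumerate(kinetics):
        e1f[ch], e2f[ch], dco[ch] = channel_propagator(kin, dt)
        e1h[ch], e2h[ch], _ = channel_propagator(kin, dt / 2.0)

    if events is None:
        ev_step = np.empty(0, np.int64)
        ev_target = np.empty(0, np.int64)
        ev_weight = np.empty(0, np.float64)
    else:
        ev_step = events.steps.astype(np.int64)
        ev_target = events.targets.astype(np.int64)
        ev_weight = events.weights.astype(np.float64)
        if ev_step.size and np.any(np.diff(ev_step) < 0):
            raise ValueError("input events must be step-sorted")

    max_delay = int(syn_delay.max()) if syn_delay.size else 1
    D = max_delay + 2
    buf_i = np.zeros((D, n))
    n_exc_syn = int((~syn_inhib).sum())
    P = max(1024, 4 * n_exc_syn)
    q_head = np.full(D, -1, dtype=np.int64)
    q_syn = np.zeros(P, dtype=np.int64)
    q_next = np.zeros(P, dtype=np.int64)
    q_free = np.zeros(P, dtype=np.int64)

    n_groups = table.n_groups
    grp_ids = [table.neurons_of(gi, excitatory=True) for gi in range(n_groups)]
    for gi, ids in enumerate(grp_ids):
        if ids.size == 0:
            raise ValueError(f"group {gi} has no excitatory neurons")
    grp_exc_ptr = np.zeros(n_groups + 1, dtype=np.int64)
    grp_exc_ptr[1:] = np.cumsum([ids.size for ids in grp_ids])
    grp_exc_ids = np.concatenate(grp_ids).astype(np.int64)

    lap_out = np.empty((n_steps, n_groups))
    cap = max(10_000, int(n * schedule.total_s * max_mean_rate_hz))
    spike_steps = np.empty(cap, dtype=np.int64)
    spike_ids = np.empty(cap, dtype=np.int64)
    v_clamp = np.full(n, -65.0)

    if record_v_ids is None:
        vrec_ids = np.empty(0, dtype=np.int64)
    else:
        vrec_ids = np.asarray(record_v_ids, dtype=np.int64)
    vrec_out = np.empty((n_steps if vrec_ids.size else 0, vrec_ids.size))

    r1 = np.zeros(syn_w.size)
    r2 = np.zeros(syn_w.size)
    last_arr = np.zeros(syn_w.size)
    o1 = np.zeros(n)
    o2 = np.zeros(n)
    last_post = np.zeros(n)

    stdp_start_ms = schedule.stdp_window_s[0] * 1e3
    stdp_end_ms = schedule.stdp_window_s[1] * 1e3

    status, n_spk = _run_kernel(
        n_steps, dt,
        a_arr, b_arr, c_arr, d_arr,
        v, u, g, x,
        e1f, e2f, e1h, e2h, dco,
        syn_ptr, syn_post, syn_w, syn_delay, syn_inhib, syn_plastic,
        in_ptr, in_idx,
        ev_step, ev_target, ev_weight,
        plasticity.a2_plus, plasticity.a2_minus, plasticity.a3_plus,
        plasticity.a3_minus, plasticity.tau_plus, plasticity.tau_minus,
        plasticity.tau_x, plasticity.tau_y, plasticity.epsilon,
        plasticity.w_min, plasticity.w_max, plastic_enabled,
        stdp_start_ms, stdp_end_ms,
        r1, r2, last_arr, o1, o2, last_post,
        q_head, q_syn, q_next, q_free,
        buf_i,
        grp_exc_ptr, grp_exc_ids,
        lap_out,
        spike_steps, spike_ids,
        v_clamp,
        vrec_ids, vrec_out,
    )
    if status == STATUS_DIVERGED:
        raise NumericalInstabilityError(
            f"membrane potential exceeded the guard after {n_spk} spikes"
        )
    if status == STATUS_SPIKE_OVERFLOW:
        raise RuntimeError(
            f"spike buffer overflow (mean rate above {max_mean_rate_hz} Hz); "
            "raise max_mean_rate_hz"
        )
    if status == STATUS_POOL_OVERFLOW:
        raise RuntimeError("delivery pool overflow; network activity pathological")

    # map weights back to the table's original synapse order
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    md = {"status": status, "n_spikes": int(n_spk)}
    if metadata:
        md.update(metadata)
    return Recording(
        spike_steps=spike_steps[:n_spk].copy(),
        spike_ids=spike_ids[:n_spk].copy(),
        lap=lap_out,
        initial_weights=initial_weights[inv],
        final_weights=syn_w[inv],
        schedule=schedule,
        table=table,
        v_trace=vrec_out if vrec_ids.size else None,
        v_trace_ids=vrec_ids if vrec_ids.size else None,
        metadata=md,
    )


def compute_lap(v_members: np.ndarray) -> np.ndarray:
    """Mean membrane potential over group members, clamped at 30 mV.

    ``v_members`` has shape (n_steps, n_members); returns one value per step.
    """
    return np.minimum(v_members, 30.0).mean(axis=1)


def downsample_lap(series: LAPSeries | np.ndarray, source_interval_ms: float | None = None,
                   target_interval_ms: float = 1.0):
    """Block-mean downsampling (non-overlapping means; anti-aliasing coarse grain).

    Accepts a :class:`LAPSeries` or a raw array plus its interval.  The target
    interval must be an integer multiple of the source interval.
    """
    if isinstance(series, LAPSeries):
        values = series.values
        src = series.interval_ms
    else:
        values = np.asarray(series, dtype=float)
        if source_interval_ms is None:
            raise ValueError("source_interval_ms required for raw arrays")
        src = source_interval_ms
    ratio = target_interval_ms / src
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError("target interval must be an integer multiple of the source interval")
    n_blocks = values.shape[0] // factor
    out = values[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)
    if isinstance(series, LAPSeries):
        return LAPSeries(values=out, interval_ms=target_interval_ms,
                         group=series.group, t_start_s=series.t_start_s)
    return out


def compute_firing_rates(
    recording: Recording, window_s: tuple[float, float]
):
    """Mean firing rate (Hz per neuron) for each (group, cell class).

    Returns a dict {(group, 'excitatory'|'inhibitory'): rate}.
    """
    s0, s1 = recording.schedule.window_steps(window_s)
    if s1 <= s0:
        raise ValueError("empty analysis window")
    dur_s = (s1 - s0) * recording.schedule.dt_ms * 1e-3
    mask = (recording.spike_steps >= s0) & (recording.spike_steps < s1)
    ids = recording.spike_ids[mask]
    table = recording.table
    out = {}
    for gi in range(table.n_groups):
        for exc, label in ((True, "excitatory"), (False, "inhibitory")):
            members = table.neurons_of(gi, excitatory=exc)
            if members.size == 0:
                continue
            count = np.isin(ids, members).sum()
            out[(gi, label)] = count / members.size / dur_s
    return out


def isi_cv(recording: Recording, window_s: tuple[float, float], excitatory: bool = True) -> float:
    """Mean coefficient of variation of per-neuron inter-spike intervals."""
    s0, s1 = recording.schedule.window_steps(window_s)
    mask = (recording.spike_steps >= s0) & (recording.spike_steps < s1)
    ids = recording.spike_ids[mask]
    steps = recording.spike_steps[mask]
    cvs = []
    for nid in np.flatnonzero(recording.table.is_excitatory == excitatory):
        st = np.sort(steps[ids == nid])
        if st.size >= 3:
            isi = np.diff(st).astype(float)
            if isi.mean() > 0:
                cvs.append(isi.std() / isi.mean())
    return float(np.mean(cvs)) if cvs else float("nan")
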