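"""Triplet spike-timing-dependent plasticity.

The rule keeps two presynaptic traces (r1, fast; r2, slow) incremented at
presynaptic spike *arrival* times, and two postsynaptic traces (o1 fast, o2
slow) incremented at postsynaptic spike times.  Weight updates:

    at a presynaptic arrival:   dw = -o1(t) [A2- + A3- r2(t - eps)]
    at a postsynaptic spike:    dw = +r1(t) [A2+ + A3+ o2(t - eps)]

with eps a small lookback (1 ms) ensuring the update reads the slow traces
before their own increment at the current event.  Weights are hard-clipped to
[w_min, w_max] after every update.  With A3+ = A3- = 0 the rule reduces to
pair-based STDP with exponential windows.

This module holds the parameter record and a transparent event-driven
reference implementation for a single synapse, used by the test suite and as
the specification for the vectorized update inside the simulation engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PlasticityParameters:
    """Triplet-rule amplitudes, trace time constants (ms) and weight bounds."""

    a2_plus: float = 5e-11
    a2_minus: float = 7e-4
    a3_plus: float = 6.2e-4
    a3_minus: float = 2.3e-5
    tau_plus: float = 16.8
    tau_minus: float = 33.7
    tau_x: float = 101.0
    tau_y: float = 125.0
    epsilon: float = 1.0
    w_min: float = 0.0
    w_max: float = 0.04

    def __post_init__(self) -> None:
        for name in ("tau_plus", "tau_minus", "tau_x", "tau_y"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("require w_min < w_max")

    def pair_based(self) -> "PlasticityParameters":
        """The pair-rule reduction (triplet amplitudes zeroed)."""
        return PlasticityParameters(
            a2_plus=self.a2_plus, a2_minus=self.a2_minus,
            a3_plus=0.0, a3_minus=0.0,
            tau_plus=self.tau_plus, tau_minus=self.tau_minus,
            tau_x=self.tau_x, tau_y=self.tau_y,
            epsilon=self.epsilon, w_min=self.w_min, w_max=self.w_max,
        )


@dataclass
class SpikeTraces:
    """Trace values of one synapse at time ``t`` (all non-negative)."""

    r1: float = 0.0
    r2: float = 0.0
    o1: float = 0.0
    o2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.r1, self.r2, self.o1, self.o2) < 0:
            raise ValueError("traces must be non-negative")


def decay_traces(traces: SpikeTraces, dt: float, params: PlasticityParameters) -> SpikeTraces:
    """Exponential decay of all four traces over ``dt`` ms (no spikes)."""
    if not dt >= 0:
        raise ValueError("dt must be non-negative")
    return SpikeTraces(
        r1=traces.r1 * math.exp(-dt / params.tau_plus),
        r2=traces.r2 * math.exp(-dt / params.tau_x),
        o1=traces.o1 * math.exp(-dt / params.tau_minus),
        o2=traces.o2 * math.exp(-dt / params.tau_y),
    )


def clip_weight(w: float, params: PlasticityParameters) -> float:
    return min(max(w, params.w_min), params.w_max)


def on_presynaptic_arrival(
    w: float,
    traces: SpikeTraces,
    params: PlasticityParameters,
    r2_lookback: float | None = None,
    active: bool = True,
) -> tuple[float, SpikeTraces]:
    """Depression at a presynaptic arrival, then r1/r2 increments.

    ``traces`` holds the values at the arrival time *before* this event's
    increments; ``r2_lookback`` optionally supplies r2(t - eps) (defaults to
    the pre-increment r2 at t).  When ``active`` is false (outside the
    plasticity schedule) the weight is untouched but traces still evolve.
    """
    r2_eff = traces.r2 if r2_lookback is None else r2_lookback
    if active:
        w = clip_weight(w - traces.o1 * (params.a2_minus + params.a3_minus * r2_eff), params)
    new = SpikeTraces(r1=traces.r1 + 1.0, r2=traces.r2 + 1.0, o1=traces.o1, o2=traces.o2)
    return w, new


def on_postsynaptic_spike(
    w: float,
    traces: SpikeTraces,
    params: PlasticityParameters,
    o2_lookback: float | None = None,
    active: bool = True,
) -> tuple[float, SpikeTraces]:
    """Potentiation at a postsynaptic spike, then o1/o2 increments."""
    o2_eff = traces.o2 if o2_lookback is None else o2_lookback
    if active:
        w = clip_weight(w + traces.r1 * (params.a2_plus + params.a3_plus * o2_eff), params)
    new = SpikeTraces(r1=traces.r1, r2=traces.r2, o1=traces.o1 + 1.0, o2=traces.o2 + 1.0)
    return w, new


def pair_ltp(delta_t: float, params: PlasticityParameters) -> float:
    """Closed-form pair potentiation for a pre->post lag ``delta_t`` > 0 ms."""
    return params.a2_plus * math.exp(-delta_t / params.tau_plus)


def pair_ltd(delta_t: float, params: PlasticityParameters) -> float:
    """Closed-form pair depression magnitude for a post->pre lag ``delta_t`` > 0 ms."""
    return params.a2_minus * math.exp(-delta_t / params.tau_minus)


def run_event_driven(
    pre_arrivals,
    post_spikes,
    w0: float,
    params: PlasticityParameters,
    window: tuple[float, float] | None = None,
    record: bool = False,
):
    """Evolve one synapse through sorted event lists (times in ms).

    ``pre_arrivals`` are presynaptic spike arrival times at the synapse (spike
    time + conduction delay); ``post_spikes`` are postsynaptic spike times.
    ``window`` restricts weight updates to [t0, t1) while traces always evolve.
    Coincident events process the postsynaptic spike first (matching the
    engine, where a spike stamped at a step boundary precedes arrivals
    delivered at the same boundary).  The slow traces are read at t - eps,
    clamped not to rewind past their last event.

    Returns the final weight, or (final weight, history list of
    (t, kind, w)) when ``record`` is true.
    """
    events = sorted(
        [(float(t), 0) for t in pre_arrivals] + [(float(t), 1) for t in post_spikes],
        key=lambda e: (e[0], -e[1]),
    )
    tr = SpikeTraces()
    t_last = 0.0
    t_last_pre = -math.inf  # last r-trace event (arrival)
    t_last_post = -math.inf
    w = float(w0)
    hist = []
    for t, kind in events:
        dt = t - t_last
        tr = decay_traces(tr, dt, params)
        active = window is None or (window[0] <= t < window[1])
        if kind == 0:
            # rewind r2 by eps ms (pre-increment value at t - eps), clamped at its last event
            rew = min(params.epsilon, max(t - t_last_pre, 0.0)) if math.isfinite(t_last_pre) else 0.0
            r2_lb = tr.r2 * math.exp(rew / params.tau_x)
            w, tr = on_presynaptic_arrival(w, tr, params, r2_lookback=r2_lb, active=active)
            t_last_pre = t
        else:
            rew = min(params.epsilon, max(t - t_last_post, 0.0)) if math.isfinite(t_last_post) else 0.0
            o2_lb = tr.o2 * math.exp(rew / params.tau_y)
            w, tr = on_postsynaptic_spike(w, tr, params, o2_lookback=o2_lb, active=active)
            t_last_post = t
        t_last = t
        if record:
            hist.append((t, "pre" if kind == 0 else "post", w))
    if record:
        return w, hist
    return w
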