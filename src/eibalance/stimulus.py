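"""Poisson input generation and the summed external-drive signal.

Every neuron receives an independent homogeneous background Poisson train
(0.6 Hz, synaptic weight 0.6) throughout the simulation.  During the external
input window, excitatory neurons of one stimulated group additionally receive
independent inhomogeneous Poisson trains with rate lambda(t) = 25 sin^2(2 pi t)
Hz (t in seconds: a 1 Hz envelope peaking at 25 Hz) and synaptic weight 0.05.
The across-train per-step sum of the external spikes is the reference signal
against which mutual information is estimated.

Generation is per-step Bernoulli thinning at the simulation step (0.05 ms),
where the homogeneous case is drawn exactly via geometric inter-spike step
counts (the count distribution of per-step Bernoulli trials) and the
inhomogeneous case by thinning a homogeneous train at the peak rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

BACKGROUND_RATE_HZ = 0.6
BACKGROUND_WEIGHT = 0.6
EXTERNAL_PEAK_RATE_HZ = 25.0
EXTERNAL_WEIGHT = 0.05


def external_input_rate(t_s):
    """Inhomogeneous external drive rate, 25 sin^2(2 pi t) Hz with t in seconds."""
    return EXTERNAL_PEAK_RATE_HZ * np.sin(2.0 * np.pi * np.asarray(t_s)) ** 2


@dataclass(frozen=True)
class PoissonInputSpec:
    """One input process: rate (Hz, constant or callable of t in seconds),
    synaptic weight, target neuron ids, and time window in seconds."""

    rate_hz: float | Callable[[np.ndarray], np.ndarray]
    weight: float
    targets: tuple[int, ...]
    t_start_s: float = 0.0
    t_stop_s: float | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("synaptic weight must be non-negative")
        if not callable(self.rate_hz) and self.rate_hz < 0:
            raise ValueError("rate must be non-negative")


def homogeneous_train_steps(
    rate_hz: float, duration_s: float, dt_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike step indices of one homogeneous train over [0, duration).

    Per-step Bernoulli with p = rate * dt; sampled exactly through geometric
    inter-spike step counts (support >= 1, so at most one spike per step).
    """
    p = rate_hz * dt_ms * 1e-3
    if p < 0:
        raise ValueError("negative rate")
    n_steps = int(round(duration_s * 1e3 / dt_ms))
    if p == 0.0 or n_steps == 0:
        return np.empty(0, dtype=np.int64)
    if p >= 1.0:
        raise ValueError("rate*dt must be below 1 for Bernoulli thinning")
    expected = int(n_steps * p)
    out = []
    pos = -1  # steps are (pos + gap), first gap counted from step 0
    while True:
        draw = max(1000, int(1.5 * (expected - sum(a.size for a in out)) + 100))
        gaps = rng.geometric(p, size=draw)
        steps = pos + np.cumsum(gaps)
        out.append(steps)
        pos = int(steps[-1])
        if pos >= n_steps:
            break
    steps = np.concatenate(out)
    return steps[steps < n_steps]


def inhomogeneous_train_steps(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    duration_s: float,
    dt_ms: float,
    rng: np.random.Generator,
    peak_rate_hz: float,
    t_offset_s: float = 0.0,
) -> np.ndarray:
    """Thinning: homogeneous candidates at the peak rate, kept w.p. lambda/peak."""
    cand = homogeneous_train_steps(peak_rate_hz, duration_s, dt_ms, rng)
    if cand.size == 0:
        return cand
    t_s = t_offset_s + cand * dt_ms * 1e-3
    lam = np.asarray(rate_fn(t_s), dtype=float)
    if np.any(lam < 0):
        raise ValueError("rate function must be non-negative")
    if np.any(lam > peak_rate_hz * (1 + 1e-9)):
        raise ValueError("rate function exceeds the stated peak rate")
    keep = rng.random(cand.size) < lam / peak_rate_hz
    return cand[keep]


def generate_poisson_train(
    spec_rate_hz, duration_s: float, dt_ms: float, rng: np.random.Generator,
    peak_rate_hz: float | None = None, t_offset_s: float = 0.0,
) -> np.ndarray:
    """Single spike train (step indices) for a constant or callable rate."""
    if callable(spec_rate_hz):
        if peak_rate_hz is None:
            raise ValueError("peak_rate_hz required for a callable rate")
        return inhomogeneous_train_steps(
            spec_rate_hz, duration_s, dt_ms, rng, peak_rate_hz, t_offset_s
        )
    return homogeneous_train_steps(float(spec_rate_hz), duration_s, dt_ms, rng)


@dataclass
class InputEvents:
    """Merged, step-sorted input events ready for the simulation engine."""

    steps: np.ndarray
    targets: np.ndarray
    weights: np.ndarray
    #: per-train spike steps of the external drive only (for the MI reference)
    external_steps: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def sorted(self) -> "InputEvents":
        order = np.argsort(self.steps, kind="stable")
        return InputEvents(
            self.steps[order], self.targets[order], self.weights[order],
            self.external_steps,
        )


def generate_inputs(
    spec: PoissonInputSpec,
    total_duration_s: float,
    dt_ms: float,
    rng: np.random.Generator,
    external: bool = False,
) -> InputEvents:
    """Independent trains, one per target neuron, merged into engine events."""
    t0 = spec.t_start_s
    t1 = total_duration_s if spec.t_stop_s is None else spec.t_stop_s
    window_s = t1 - t0
    offset_steps = int(round(t0 * 1e3 / dt_ms))
    steps_l, tgt_l = [], []
    peak = EXTERNAL_PEAK_RATE_HZ if callable(spec.rate_hz) else None
    for tgt in spec.targets:
        s = generate_poisson_train(
            spec.rate_hz, window_s, dt_ms, rng, peak_rate_hz=peak, t_offset_s=t0
        )
        steps_l.append(s + offset_steps)
        tgt_l.append(np.full(s.size, tgt, dtype=np.int32))
    steps = np.concatenate(steps_l) if steps_l else np.empty(0, np.int64)
    targets = np.concatenate(tgt_l) if tgt_l else np.empty(0, np.int32)
    ev = InputEvents(
        steps=steps.astype(np.int64),
        targets=targets,
        weights=np.full(steps.size, spec.weight),
        external_steps=steps.astype(np.int64) if external else np.empty(0, np.int64),
    )
    return ev.sorted()


def merge_events(*event_sets: InputEvents) -> InputEvents:
    ext = [e.external_steps for e in event_sets if e.external_steps.size]
    merged = InputEvents(
        steps=np.concatenate([e.steps for e in event_sets]),
        targets=np.concatenate([e.targets for e in event_sets]),
        weights=np.concatenate([e.weights for e in event_sets]),
        external_steps=np.concatenate(ext) if ext else np.empty(0, np.int64),
    )
    return merged.sorted()


def external_drive_signal(
    spike_steps: np.ndarray, start_step: int, n_steps: int
) -> np.ndarray:
    """Summed external input per simulation step over a window.

    One non-negative integer per step; the series total equals the number of
    spikes falling inside the window.
    """
    rel = np.asarray(spike_steps, dtype=np.int64) - start_step
    rel = rel[(rel >= 0) & (rel < n_steps)]
    return np.bincount(rel, minlength=n_steps).astype(np.int64)
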