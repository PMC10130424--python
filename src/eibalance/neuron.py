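"""Izhikevich point neurons with conductance-based AMPA/NMDA/GABA synapses.

The membrane follows the two-variable quadratic integrate model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_syn
    du/dt = a (b v - u)

with the hard reset v <- c, u <- u + d whenever v reaches 30 mV.  Excitatory
cells use the regular-spiking (RS) parameter set and inhibitory cells the
fast-spiking (FS) set.  Synaptic input is conductance based: each of the three
channels (AMPA, NMDA, GABA) is a linear two-variable cascade

    dx/dt = -x / tau2          x <- x + w on presynaptic arrival
    dg/dt = (K x - g) / tau1

whose impulse response is a difference of exponentials.  K is chosen so that a
unit-weight impulse produces a unit peak conductance, making synaptic weights
directly interpretable as peak conductances.  The NMDA current carries the
standard magnesium-block voltage dependence; GABA reverses at -70 mV.

Units: time in ms, potentials in mV.  All functions here are pure; the
time-stepped network loop lives in :mod:`eibalance.engine` and reproduces the
same per-step arithmetic (exact exponential channel propagation, classical RK4
on (v, u) with channel states evaluated at the substage times, reset checked
once per full step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

SPIKE_THRESHOLD_MV = 30.0
#: divergence guard for the integrator (numerical-instability error above this)
V_GUARD_MV = 1.0e3

#: channel indices used throughout the package
AMPA, NMDA, GABA = 0, 1, 2


class InvalidStateError(ValueError):
    """Raised when a dynamical state contains non-finite values."""


class NumericalInstabilityError(RuntimeError):
    """Raised when the membrane potential exceeds the divergence guard."""


@dataclass(frozen=True)
class NeuronParameters:
    """Izhikevich model constants for one cell class.

    a : recovery time scale (1/ms); b : recovery sensitivity; c : reset
    potential (mV); d : recovery increment at reset.
    """

    a: float
    b: float
    c: float
    d: float
    cell_class: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("recovery time scale a must be positive")
        if not self.c < SPIKE_THRESHOLD_MV:
            raise ValueError("reset potential c must lie below the 30 mV threshold")


#: canonical regular-spiking (excitatory) parameter set
REGULAR_SPIKING = NeuronParameters(a=0.02, b=0.2, c=-65.0, d=8.0, cell_class="excitatory-RS")
#: canonical fast-spiking (inhibitory) parameter set
FAST_SPIKING = NeuronParameters(a=0.1, b=0.2, c=-65.0, d=2.0, cell_class="inhibitory-FS")


@dataclass(frozen=True)
class ChannelKinetics:
    """Rise/decay constants of one conductance channel (ms).

    ``gain`` rescales the normalized impulse response; ``None`` selects the
    unit-peak normalization K = 1 / peak(unit impulse response).
    """

    tau1: float
    tau2: float
    gain: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.tau1 < self.tau2):
            raise ValueError("require 0 < tau1 < tau2")

    @property
    def peak_time(self) -> float:
        """Time to peak of the impulse response, (tau1 tau2/(tau2-tau1)) ln(tau2/tau1)."""
        t1, t2 = self.tau1, self.tau2
        return t1 * t2 / (t2 - t1) * math.log(t2 / t1)

    @property
    def normalization(self) -> float:
        """Gain K such that a unit-weight impulse yields the requested peak."""
        if self.gain is not None:
            return self.gain
        t1, t2 = self.tau1, self.tau2
        tp = self.peak_time
        raw_peak = t2 / (t2 - t1) * (math.exp(-tp / t2) - math.exp(-tp / t1))
        return 1.0 / raw_peak


AMPA_KINETICS = ChannelKinetics(0.5, 2.4)
NMDA_KINETICS = ChannelKinetics(4.0, 40.0)
GABA_KINETICS = ChannelKinetics(1.0, 7.0)
DEFAULT_KINETICS = (AMPA_KINETICS, NMDA_KINETICS, GABA_KINETICS)


@dataclass
class NeuronState:
    """Membrane state plus (g, x) for each of the three channels."""

    v: float
    u: float
    g: np.ndarray = field(default_factory=lambda: np.zeros(3))
    x: np.ndarray = field(default_factory=lambda: np.zeros(3))


def initial_state(params: NeuronParameters) -> NeuronState:
    """Standard initialization: v = -65 mV, u = b v, silent channels."""
    v0 = -65.0
    return NeuronState(v=v0, u=params.b * v0)


def membrane_derivatives(
    v: float, u: float, params: NeuronParameters, i_syn: float
) -> tuple[float, float]:
    """Right-hand sides (dv/dt, du/dt) of the membrane equations."""
    if not (math.isfinite(v) and math.isfinite(u) and math.isfinite(i_syn)):
        raise InvalidStateError("non-finite membrane state or current")
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_syn
    du = params.a * (params.b * v - u)
    return dv, du


def apply_spike_reset(
    v: float, u: float, params: NeuronParameters
) -> tuple[float, float, bool]:
    """Apply the v >= 30 mV reset; returns (v, u, spiked)."""
    if v >= SPIKE_THRESHOLD_MV:
        return params.c, u + params.d, True
    return v, u, False


def synaptic_current(v: float, g_ampa: float, g_nmda: float, g_gaba: float) -> float:
    """Total synaptic current at potential ``v``.

    AMPA and NMDA reverse at 0 mV, GABA at -70 mV; the NMDA term is gated by
    the sigmoidal magnesium block s/(1+s) with s = ((v+80)/60)^2.
    """
    s = ((v + 80.0) / 60.0) ** 2
    return g_ampa * (0.0 - v) + g_nmda * s / (1.0 + s) * (0.0 - v) + g_gaba * (-70.0 - v)


def channel_propagator(kin: ChannelKinetics, dt: float) -> tuple[float, float, float]:
    """Exact one-step linear map coefficients (e1, e2, dcoef) for (g, x).

    g(t+dt) = g e1 + dcoef * x * (e2 - e1);  x(t+dt) = x e2,
    with dcoef = K tau2 / (tau2 - tau1).
    """
    e1 = math.exp(-dt / kin.tau1)
    e2 = math.exp(-dt / kin.tau2)
    dcoef = kin.normalization * kin.tau2 / (kin.tau2 - kin.tau1)
    return e1, e2, dcoef


def update_channel(
    g: float, x: float, kin: ChannelKinetics, dt: float, arrival_weight: float = 0.0
) -> tuple[float, float]:
    """Advance one channel a step of ``dt``; spike arrivals add weight to x first."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    x = x + arrival_weight
    e1, e2, dcoef = channel_propagator(kin, dt)
    g_new = g * e1 + dcoef * x * (e2 - e1)
    return g_new, x * e2


def impulse_response(kin: ChannelKinetics, t, w: float = 1.0):
    """Closed-form conductance response g(t) to an impulse of weight ``w`` at t=0."""
    t = np.asarray(t, dtype=float)
    dcoef = kin.normalization * kin.tau2 / (kin.tau2 - kin.tau1)
    return w * dcoef * (np.exp(-t / kin.tau2) - np.exp(-t / kin.tau1))


def rk4_step(
    state: NeuronState,
    params: NeuronParameters,
    kinetics: tuple[ChannelKinetics, ...] = DEFAULT_KINETICS,
    dt: float = 0.05,
    arrivals: np.ndarray | None = None,
) -> tuple[NeuronState, bool]:
    """Advance a neuron one full step; mirrors the network engine exactly.

    ``arrivals`` optionally adds weight to each channel's x gate before the
    step (delivery happens at step start).  The channel cascade is linear and
    independent of v, so it is propagated with its exact exponential solution
    and the RK4 substages read the channel values at t, t+dt/2 and t+dt.
    The reset is checked once after the full step.
    """
    g0 = state.g.copy()
    x0 = state.x.copy()
    if arrivals is not None:
        x0 = x0 + arrivals
    g_half = np.empty(3)
    g_full = np.empty(3)
    x_full = np.empty(3)
    for ch, kin in enumerate(kinetics):
        e1h, e2h, dco = channel_propagator(kin, dt / 2.0)
        e1f, e2f, _ = channel_propagator(kin, dt)
        g_half[ch] = g0[ch] * e1h + dco * x0[ch] * (e2h - e1h)
        g_full[ch] = g0[ch] * e1f + dco * x0[ch] * (e2f - e1f)
        x_full[ch] = x0[ch] * e2f

    def f(v: float, u: float, g: np.ndarray) -> tuple[float, float]:
        i_syn = synaptic_current(v, g[AMPA], g[NMDA], g[GABA])
        return membrane_derivatives(v, u, params, i_syn)

    v, u = state.v, state.u
    k1v, k1u = f(v, u, g0)
    k2v, k2u = f(v + 0.5 * dt * k1v, u + 0.5 * dt * k1u, g_half)
    k3v, k3u = f(v + 0.5 * dt * k2v, u + 0.5 * dt * k2u, g_half)
    k4v, k4u = f(v + dt * k3v, u + dt * k3u, g_full)
    v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    u_new = u + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
    if v_new > V_GUARD_MV:
        raise NumericalInstabilityError(f"membrane potential diverged: v={v_new:.3g} mV")
    v_new, u_new, spiked = apply_spike_reset(v_new, u_new, params)
    return NeuronState(v=v_new, u=u_new, g=g_full, x=x_full), spiked


@njit(cache=True)
def _integrate_constant_current(
    a: float,
    b: float,
    c: float,
    d: float,
    i_syn: float,
    dt: float,
    n_steps: int,
    v0: float,
    u0: float,
):  # pragma: no cover - exercised through simulate_constant_current
    v_trace = np.empty(n_steps + 1)
    spike_times = np.empty(n_steps)
    n_spk = 0
    v, u = v0, u0
    v_trace[0] = v
    for step in range(n_steps):
        k1v = 0.04 * v * v + 5.0 * v + 140.0 - u + i_syn
        k1u = a * (b * v - u)
        v1 = v + 0.5 * dt * k1v
        u1 = u + 0.5 * dt * k1u
        k2v = 0.04 * v1 * v1 + 5.0 * v1 + 140.0 - u1 + i_syn
        k2u = a * (b * v1 - u1)
        v2 = v + 0.5 * dt * k2v
        u2 = u + 0.5 * dt * k2u
        k3v = 0.04 * v2 * v2 + 5.0 * v2 + 140.0 - u2 + i_syn
        k3u = a * (b * v2 - u2)
        v3 = v + dt * k3v
        u3 = u + dt * k3u
        k4v = 0.04 * v3 * v3 + 5.0 * v3 + 140.0 - u3 + i_syn
        k4u = a * (b * v3 - u3)
        v = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        u = u + dt / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        if v >= 30.0:
            spike_times[n_spk] = (step + 1) * dt
            n_spk += 1
            v = c
            u = u + d
        v_trace[step + 1] = v
    return v_trace, spike_times[:n_spk]


def simulate_constant_current(
    params: NeuronParameters,
    i_syn: float,
    duration_ms: float,
    dt: float = 0.05,
    v0: float | None = None,
    u0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate an isolated neuron under constant injected current.

    Returns (v trace at step boundaries, spike times in ms).  Used both as a
    convenience and, at small dt, as a reference integration for convergence
    checks.
    """
    if v0 is None:
        v0 = -65.0
    if u0 is None:
        u0 = params.b * v0
    n_steps = int(round(duration_ms / dt))
    v_trace, spikes = _integrate_constant_current(
        params.a, params.b, params.c, params.d, float(i_syn), float(dt), n_steps, float(v0), float(u0)
    )
    if np.max(v_trace) > V_GUARD_MV:
        raise NumericalInstabilityError("membrane potential diverged")
    return v_trace, spikes
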