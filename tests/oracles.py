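"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: the sample
entropy oracle is a direct double-loop transliteration of the definition, and
the plasticity oracle integrates the four traces on a dense time grid instead
of using event-driven exponential updates.
"""

import math

import numpy as np


def sample_entropy_bruteforce(y, m, r):
    """Direct template-pair counting per the printed definition.

    C_m over the (N-m+1) length-m templates, C_{m+1} over the (N-m)
    length-(m+1) templates, Chebyshev distance strictly below r, i != j,
    normalized by (count)(count-1) ordered pairs... returned as
    -ln(C_{m+1}/C_m), NaN when either count is zero.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)

    def pair_fraction(length):
        n_templates = n - length + 1
        hits = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if i == j:
                    continue
                if max(abs(y[i + k] - y[j + k]) for k in range(length)) < r:
                    hits += 1
        return hits / (n_templates * (n_templates - 1))

    c_m = pair_fraction(m)
    c_m1 = pair_fraction(m + 1)
    if c_m == 0 or c_m1 == 0:
        return float("nan")
    return -math.log(c_m1 / c_m)


def triplet_stdp_dense_grid(
    pre_arrivals, post_spikes, w0, params, grid_dt=0.001, window=None
):
    """Integrate the four STDP traces on a dense grid and replay the rule.

    Spike times must be multiples of ``grid_dt``.  Traces decay by
    exp(-grid_dt/tau) each step; at a presynaptic arrival the weight is
    depressed using o1(t) and r2(t - eps) (the grid value eps ms back,
    before this arrival's increment), then r1 and r2 are incremented;
    symmetrically for postsynaptic spikes.  Coincident events process the
    postsynaptic spike first, matching the event-driven implementation.
    """
    events = sorted(
        [(round(t / grid_dt), 0) for t in pre_arrivals]
        + [(round(t / grid_dt), 1) for t in post_spikes],
        key=lambda e: (e[0], -e[1]),
    )
    if not events:
        return w0
    eps_steps = int(round(params.epsilon / grid_dt))
    dr1 = math.exp(-grid_dt / params.tau_plus)
    dr2 = math.exp(-grid_dt / params.tau_x)
    do1 = math.exp(-grid_dt / params.tau_minus)
    do2 = math.exp(-grid_dt / params.tau_y)
    n_steps = events[-1][0] + 1
    r1 = r2 = o1 = o2 = 0.0
    # ring buffers of the slow-trace history for the eps lookback
    r2_hist = np.zeros(eps_steps + 1)
    o2_hist = np.zeros(eps_steps + 1)
    w = float(w0)
    ev = 0
    for step in range(n_steps):
        if step > 0:
            r1 *= dr1
            r2 *= dr2
            o1 *= do1
            o2 *= do2
        r2_hist[step % (eps_steps + 1)] = r2
        o2_hist[step % (eps_steps + 1)] = o2
        while ev < len(events) and events[ev][0] == step:
            t_ms = step * grid_dt
            active = window is None or (window[0] <= t_ms < window[1])
            back = (step - eps_steps) % (eps_steps + 1)
            if events[ev][1] == 0:
                if active:
                    r2_eps = r2_hist[back] if step >= eps_steps else 0.0
                    w = max(w - o1 * (params.a2_minus + params.a3_minus * r2_eps), params.w_min)
                r1 += 1.0
                r2 += 1.0
                r2_hist[step % (eps_steps + 1)] = r2
            else:
                if active:
                    o2_eps = o2_hist[back] if step >= eps_steps else 0.0
                    w = min(w + r1 * (params.a2_plus + params.a3_plus * o2_eps), params.w_max)
                o1 += 1.0
                o2 += 1.0
                o2_hist[step % (eps_steps + 1)] = o2
            ev += 1
    return w


def poisson_trains_with_refractory(rng, n_trains, rate_hz, duration_ms, refractory_ms=2.0):
    """Random spike trains on the 0.05 ms grid with a minimum ISI."""
    trains = []
    for _ in range(n_trains):
        t = 0.0
        spikes = []
        while True:
            t += refractory_ms + rng.exponential(1000.0 / rate_hz)
            t_snap = round(t / 0.05) * 0.05
            if t_snap >= duration_ms:
                break
            spikes.append(t_snap)
        trains.append(np.array(spikes))
    return trains
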