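"""Synthetic fixtures with known statistical structure.

Every generator is seed-deterministic and returns its analytic ground truth
alongside the data, so estimator tests never recompute expectations inline:

* correlated Gaussian pairs — MI = -0.5 ln(1 - rho^2);
* coupled autoregressive pairs  Y_t = a Y_{t-1} + b X_{t-1} + e_t  with X
  white unit-variance — TE_{X->Y} = 0.5 ln(1 + b^2), TE_{Y->X} = 0;
* equal-variance reference signals (white noise, sine, 1/f-like noise) with
  the documented multiscale-entropy ordering;
* miniature network presets: desk-scale twins of the two-group and ten-group
  study configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SurrogatePair:
    """A generated pair plus its analytic ground truth values."""

    x: np.ndarray
    y: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)


def correlated_gaussian_pair(rho: float, n: int, seed: int) -> SurrogatePair:
    """Zero-mean unit-variance Gaussian pair with correlation ``rho``."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be below 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = z1
    y = rho * z1 + math.sqrt(1.0 - rho * rho) * z2
    return SurrogatePair(
        x=x, y=y, kind="correlated-gaussian",
        params={"rho": rho, "n": n, "seed": seed},
        ground_truth={"mi_nats": -0.5 * math.log(1.0 - rho * rho)},
    )


def coupled_ar_pair(alpha: float, beta: float, n: int, seed: int) -> SurrogatePair:
    """X white unit-variance; Y_t = alpha Y_{t-1} + beta X_{t-1} + unit noise.

    Stationary algebra: Var(Y) = (1 + beta^2)/(1 - alpha^2); the best linear
    one-step predictor of Y from its own past leaves residual variance
    Var(Y)(1 - alpha^2) = 1 + beta^2, while adding X's past reduces it to the
    innovation variance 1, so TE_{X->Y} = 0.5 ln(1 + beta^2).  X is
    autonomous, so TE_{Y->X} = 0.
    """
    if not abs(alpha) < 1:
        raise ValueError("|alpha| must be below 1 for stationarity")
    rng = np.random.default_rng(seed)
    burn = 200
    x = rng.standard_normal(n + burn)
    e = rng.standard_normal(n + burn)
    y = np.zeros(n + burn)
    for t in range(1, n + burn):
        y[t] = alpha * y[t - 1] + beta * x[t - 1] + e[t]
    return SurrogatePair(
        x=x[burn:], y=y[burn:], kind="coupled-ar",
        params={"alpha": alpha, "beta": beta, "n": n, "seed": seed},
        ground_truth={
            "te_xy_nats": 0.5 * math.log(1.0 + beta * beta),
            "te_yx_nats": 0.0,
            "var_y": (1.0 + beta * beta) / (1.0 - alpha * alpha),
        },
    )


def te_by_regression(pair: SurrogatePair) -> float:
    """Empirical linear-Gaussian TE of a coupled-AR pair via residual variances.

    Independent oracle for the covariance formula: ratio of the one-step
    prediction residual variance of Y from its own past alone to that from
    (own past, X past).
    """
    x, y = pair.x, pair.y
    y_fut, y_past, x_past = y[1:], y[:-1], x[:-1]
    # reduced model: Y_{t+1} ~ Y_t
    A = np.column_stack([y_past, np.ones_like(y_past)])
    res_red = y_fut - A @ np.linalg.lstsq(A, y_fut, rcond=None)[0]
    # full model: Y_{t+1} ~ (Y_t, X_t)
    B = np.column_stack([y_past, x_past, np.ones_like(y_past)])
    res_full = y_fut - B @ np.linalg.lstsq(B, y_fut, rcond=None)[0]
    return 0.5 * math.log(res_red.var() / res_full.var())


def reference_signals(n: int, seed: int) -> dict[str, np.ndarray]:
    """White noise, sine and 1/f-like noise with matched (unit) variance.

    Documented multiscale-entropy ordering: white-noise entropy decreases
    with scale, 1/f noise stays comparatively flat, and the sine is low at
    every scale.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)

    t = np.arange(n)
    # well above-Nyquist sampling of a pure tone (64 samples per cycle)
    sine = np.sin(2.0 * np.pi * t / 64.0)

    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    pink = np.fft.irfft(spec / np.sqrt(freqs), n)

    out = {}
    for name, sig in (("white", white), ("sine", sine), ("pink", pink)):
        sig = sig - sig.mean()
        out[name] = sig / sig.std()
    return out


def mini_network_preset(name: str, scale: float = 0.125):
    """Desk-scale experiment configuration twins of the study setups.

    Group sizes are scaled by ``scale`` (baseline 100 E + 25 I at the default
    1/8) while per-neuron out-degrees, dt, channel kinetics, plasticity
    constants and weight bounds keep their full-scale values, so each
    neuron's expected synaptic drive matches the full-size regime.
    """
    from .experiments import ring_config, two_group_config

    if name == "two-group-small":
        return two_group_config(scale=scale)
    if name == "ring-ten-small":
        return ring_config("B", scale=scale)
    raise ValueError(f"unknown preset {name!r}; use 'two-group-small' or 'ring-ten-small'")
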