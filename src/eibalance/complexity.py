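"""Multiscale entropy: coarse-graining, sample entropy, complexity index.

Sample entropy is the negative log of the conditional probability that
subsequences matching for m points (Chebyshev distance strictly below r,
self-matches excluded) also match for m+1 points:

    SampEn(r, m, N) = -ln( C_{m+1}(r) / C_m(r) )
    C_m(r) = #{(i, j) : i != j, max_k |y_{i+k} - y_{j+k}| < r} / ((N-m+1)(N-m))

computed over all templates of the given length.  Multiscale entropy evaluates
SampEn on progressively coarse-grained (non-overlapping block-mean) copies of
the signal; the complexity index is the sum over scales 1..max_scale.  The
tolerance r is fixed at r_factor times the SD of the original (scale-1)
signal and reused at every scale, the standard convention.

Scales where no template pair matches (C = 0) yield an undefined entropy;
they are flagged and excluded from the index rather than silently replaced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass(frozen=True)
class MSEParameters:
    """Template length m, SD-relative tolerance, and number of scales."""

    m: int = 2
    r_factor: float = 0.15
    max_scale: int = 100

    def __post_init__(self) -> None:
        if self.m < 1 or self.r_factor <= 0 or self.max_scale < 1:
            raise ValueError("require m >= 1, r > 0, max_scale >= 1")


@dataclass
class MSEResult:
    """Per-scale entropies with validity flags and their sum."""

    scales: np.ndarray
    entropy: np.ndarray  # NaN where undefined
    valid: np.ndarray
    r_abs: float
    truncated: bool = False

    @property
    def complexity_index(self) -> float:
        return float(np.nansum(np.where(self.valid, self.entropy, 0.0)))


def coarse_grain(signal: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping block means of length ``scale`` (length floor(N/scale))."""
    signal = np.asarray(signal, dtype=float)
    if scale < 1 or scale > signal.shape[0]:
        raise ValueError("scale must lie in [1, len(signal)]")
    n_blocks = signal.shape[0] // scale
    return signal[: n_blocks * scale].reshape(n_blocks, scale).mean(axis=1)


@njit(cache=True)
def _template_counts(y, m, r):  # pragma: no cover - numba
    """Matched pair counts at lengths m and m+1 per the printed normalization."""
    n = y.shape[0]
    count_m = 0
    count_m1 = 0
    n_tm = n - m + 1   # templates of length m
    n_tm1 = n - m      # templates of length m+1
    for i in range(n_tm):
        for j in range(i + 1, n_tm):
            match = True
            for k in range(m):
                d = abs(y[i + k] - y[j + k])
                if d >= r:
                    match = False
                    break
            if match:
                count_m += 1
                if i < n_tm1 and j < n_tm1:
                    if abs(y[i + m] - y[j + m]) < r:
                        count_m1 += 1
    return count_m, count_m1


def sample_entropy(signal: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy in nats; NaN when no template pair matches (undefined)."""
    y = np.asarray(signal, dtype=float)
    n = y.shape[0]
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be a positive tolerance")
    b, a = _template_counts(y, m, float(r_abs))
    if b == 0 or a == 0:
        return float("nan")
    n_tm = n - m + 1
    n_tm1 = n - m
    c_m = 2.0 * b / (n_tm * (n_tm - 1))
    c_m1 = 2.0 * a / (n_tm1 * (n_tm1 - 1))
    return -math.log(c_m1 / c_m)


def mse_curve(signal: np.ndarray, params: MSEParameters = MSEParameters()) -> MSEResult:
    """Per-scale sample entropy and the summed complexity index.

    If the signal is too short for ``max_scale`` (fewer than m+2 coarse
    samples), the usable range is reduced and the result flagged truncated.
    """
    y = np.asarray(signal, dtype=float)
    r_abs = params.r_factor * float(np.std(y))
    if r_abs <= 0:
        raise ValueError("signal has zero variance; tolerance undefined")
    usable = min(params.max_scale, y.shape[0] // (params.m + 2))
    truncated = usable < params.max_scale
    scales = np.arange(1, params.max_scale + 1)
    entropy = np.full(params.max_scale, np.nan)
    for s in range(1, usable + 1):
        entropy[s - 1] = sample_entropy(coarse_grain(y, s), params.m, r_abs)
    valid = np.isfinite(entropy)
    return MSEResult(scales=scales, entropy=entropy, valid=valid,
                     r_abs=r_abs, truncated=truncated)
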