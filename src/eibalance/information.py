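"""k-nearest-neighbour (KSG) mutual information and transfer entropy.

Mutual information between continuous series uses the Kraskov-Stogbauer-
Grassberger algorithm 1: with eps_i the Chebyshev distance of joint sample i
to its k-th neighbour and n_x, n_y the marginal neighbour counts strictly
inside eps_i,

    MI = psi(k) + psi(N) - < psi(n_x + 1) + psi(n_y + 1) >.

Transfer entropy from a source series S to a target series T with history
lengths l and k_hist is the conditional mutual information
I(T_{t+1}; S_t^{(l)} | T_t^{(k_hist)}) computed with the KSG-style conditional
estimator (Frenzel-Pompe):

    TE = psi(k) + < psi(n_z + 1) - psi(n_xz + 1) - psi(n_yz + 1) >

where z is the conditioning (target-history) block.  A seeded uniform jitter
of amplitude 1e-10 x SD per coordinate breaks distance ties, making estimates
bit-reproducible for a fixed seed.  All results are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma


class DegenerateInputError(ValueError):
    """Raised when an input series is constant (estimator undefined)."""


@dataclass(frozen=True)
class EmbeddingSpec:
    """History lengths for transfer entropy: source l, target k_hist samples,
    one-step prediction horizon, and the neighbour count of the estimator."""

    l: int = 1
    k_hist: int = 140
    horizon: int = 1
    k_nn: int = 4

    def __post_init__(self) -> None:
        if self.l < 1 or self.k_hist < 1 or self.horizon < 1 or self.k_nn < 1:
            raise ValueError("all embedding parameters must be >= 1")


def _as_columns(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def _jitter(a: np.ndarray, rng: np.random.Generator, scale: float = 1e-10) -> np.ndarray:
    sd = a.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateInputError("constant input series")
    return a + rng.uniform(-1.0, 1.0, size=a.shape) * (scale * sd)


def _strict_counts(tree: cKDTree, pts: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Number of points (excluding self) strictly within Chebyshev radius eps."""
    r = np.nextafter(eps, 0.0)
    return np.asarray(
        tree.query_ball_point(pts, r, p=np.inf, return_length=True), dtype=float
    ) - 1.0


def ksg_mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    k_nn: int = 4,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """KSG algorithm-1 MI estimate between ``x`` and ``y`` (nats).

    Accepts 1-d series or (N, d) blocks of equal length N >= 50.
    """
    x = _as_columns(x)
    y = _as_columns(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("series must have equal length")
    n = x.shape[0]
    if n < 50:
        raise ValueError("need at least 50 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _jitter(x, rng)
    y = _jitter(y, rng)
    z = np.hstack([x, y])
    tree = cKDTree(z)
    eps = tree.query(z, k=k_nn + 1, p=np.inf)[0][:, -1]
    nx = _strict_counts(cKDTree(x), x, eps)
    ny = _strict_counts(cKDTree(y), y, eps)
    return float(
        digamma(k_nn) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


def ksg_conditional_mi(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    k_nn: int = 4,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Conditional MI I(x; y | z) via the KSG-style (Frenzel-Pompe) estimator."""
    x = _as_columns(x)
    y = _as_columns(y)
    z = _as_columns(z)
    n = x.shape[0]
    if not (y.shape[0] == n and z.shape[0] == n):
        raise ValueError("blocks must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _jitter(x, rng)
    y = _jitter(y, rng)
    z = _jitter(z, rng)
    joint = np.hstack([x, y, z])
    xz = np.hstack([x, z])
    yz = np.hstack([y, z])
    tree = cKDTree(joint)
    eps = tree.query(joint, k=k_nn + 1, p=np.inf)[0][:, -1]
    n_xz = _strict_counts(cKDTree(xz), xz, eps)
    n_yz = _strict_counts(cKDTree(yz), yz, eps)
    n_z = _strict_counts(cKDTree(z), z, eps)
    return float(
        digamma(k_nn)
        + np.mean(digamma(n_z + 1) - digamma(n_xz + 1) - digamma(n_yz + 1))
    )


def _embed_history(series: np.ndarray, length: int, t_idx: np.ndarray) -> np.ndarray:
    """History blocks [s_{t-length+1} .. s_t] for each t in t_idx."""
    cols = [series[t_idx - lag] for lag in range(length - 1, -1, -1)]
    return np.column_stack(cols)


def transfer_entropy(
    source: np.ndarray,
    target: np.ndarray,
    spec: EmbeddingSpec = EmbeddingSpec(k_hist=1),
    seed: int | np.random.Generator | None = 0,
) -> float:
    """History-embedded transfer entropy source -> target (nats)."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape[0] != target.shape[0]:
        raise ValueError("series must have equal length")
    n = source.shape[0]
    t_min = max(spec.k_hist, spec.l) - 1
    t_max = n - 1 - spec.horizon
    n_emb = t_max - t_min + 1
    if n_emb < spec.k_nn + 2:
        raise ValueError(
            f"need at least {t_min + spec.horizon + spec.k_nn + 2} samples for "
            f"this embedding, got {n}"
        )
    t_idx = np.arange(t_min, t_max + 1)
    fut = target[t_idx + spec.horizon][:, None]
    src_hist = _embed_history(source, spec.l, t_idx)
    tgt_hist = _embed_history(target, spec.k_hist, t_idx)
    return ksg_conditional_mi(fut, src_hist, tgt_hist, k_nn=spec.k_nn, seed=seed)


@dataclass
class InformationResult:
    """Per-group MI against the external drive and per-pair TE (nats)."""

    mi: dict = field(default_factory=dict)           # group -> MI
    te: dict = field(default_factory=dict)           # (src_group, dst_group) -> TE
    stimulated_group: int = 0
    metadata: dict = field(default_factory=dict)


def information_pipeline(
    recording,
    drive_signal: np.ndarray,
    stimulated_group: int,
    spec: EmbeddingSpec | None = None,
    sample_interval_ms: float = 1.0,
    seed: int | np.random.Generator | None = 0,
) -> InformationResult:
    """MI(LAP_i; drive) for every group and TE(LAP_stim -> LAP_j) for j != stim.

    Series are restricted to the external-input window and resampled to
    ``sample_interval_ms`` by block means (drive counts are block-summed).
    The target-history length follows the 7 ms rule: k_hist =
    7 ms / sample interval unless a spec is supplied.
    """
    from .engine import downsample_lap

    schedule = recording.schedule
    s0, s1 = schedule.window_steps(schedule.input_window_s)
    if drive_signal.shape[0] != s1 - s0:
        raise ValueError("drive signal must cover the external-input window")
    factor = int(round(sample_interval_ms / schedule.dt_ms))
    if spec is None:
        spec = EmbeddingSpec(l=1, k_hist=max(1, int(round(7.0 / sample_interval_ms))))
    n_groups = recording.table.n_groups
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_blocks = drive_signal.shape[0] // factor
    drive = drive_signal[: n_blocks * factor].reshape(n_blocks, factor).sum(axis=1).astype(float)

    laps = {}
    for gi in range(n_groups):
        lap = recording.lap[s0:s1, gi]
        laps[gi] = downsample_lap(lap, schedule.dt_ms, sample_interval_ms) if factor > 1 else lap

    result = InformationResult(
        stimulated_group=stimulated_group,
        metadata={
            "k_nn": spec.k_nn, "l": spec.l, "k_hist": spec.k_hist,
            "sample_interval_ms": sample_interval_ms,
            "jitter_scale": 1e-10,
        },
    )
    for gi in range(n_groups):
        result.mi[gi] = ksg_mutual_information(
            laps[gi], drive, k_nn=spec.k_nn, seed=np.random.default_rng(rng.integers(2**31))
        )
    for gj in range(n_groups):
        if gj == stimulated_group:
            continue
        result.te[(stimulated_group, gj)] = transfer_entropy(
            laps[stimulated_group], laps[gj], spec,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
    return result
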