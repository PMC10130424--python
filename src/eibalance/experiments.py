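"""Condition grids, presets, multi-seed orchestration and statistics.

The two-group protocol varies the inhibitory-neuron count N_I in
{100, 150, 200, 250, 300} and the inhibitory-to-excitatory weight W_IE in
{0.0125, 0.01875, 0.025, 0.03125, 0.0375} in group 1 (the imbalanced group)
while group 2 stays at the baseline (200, 0.025).  The named presets are
H-E/I = (100, 0.0125) (weak inhibition), B-E/I = (200, 0.025) and
L-E/I = (300, 0.0375) (strong inhibition).  The ten-group protocol places the
imbalanced group on a ring where every group connects to its four nearest
neighbours, and feeds the external input to one group.

Each run reports mean intra/inter excitatory weights, per-class firing rates,
the multiscale-entropy complexity index per group and, when an external input
is scheduled, MI/TE of the group activity.  Conditions are compared against
baseline with Welch's t-tests (as in the study figures) or one-sided
Mann-Whitney rank tests for the desk-scale directional checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .complexity import MSEParameters, mse_curve
from .engine import (
    Recording,
    SimulationSchedule,
    compute_firing_rates,
    downsample_lap,
    isi_cv,
    run_simulation,
)
from .information import EmbeddingSpec, information_pipeline
from .network import (
    GroupSpec,
    build_network,
    ring_topology,
    summarize_weights,
    two_group_topology,
)
from .stdp import PlasticityParameters
from .stimulus import (
    BACKGROUND_RATE_HZ,
    BACKGROUND_WEIGHT,
    EXTERNAL_WEIGHT,
    InputEvents,
    PoissonInputSpec,
    external_drive_signal,
    external_input_rate,
    generate_inputs,
    merge_events,
)

#: the study's condition axes and named presets (N_I, W_IE)
N_I_VALUES = (100, 150, 200, 250, 300)
W_IE_VALUES = (0.0125, 0.01875, 0.025, 0.03125, 0.0375)
BASELINE = (200, 0.025)
PRESETS = {"H": (100, 0.0125), "B": (200, 0.025), "L": (300, 0.0375)}


@dataclass(frozen=True)
class ConditionGrid:
    n_i_values: tuple = N_I_VALUES
    w_ie_values: tuple = W_IE_VALUES
    baseline: tuple = BASELINE
    presets: dict = field(default_factory=lambda: dict(PRESETS))
    runs_per_condition: int = 20

    def __post_init__(self) -> None:
        if self.baseline[0] not in self.n_i_values or self.baseline[1] not in self.w_ie_values:
            raise ValueError("baseline must be a grid cell")
        for p in self.presets.values():
            if p[0] not in self.n_i_values or p[1] not in self.w_ie_values:
                raise ValueError("presets must be grid cells")

    @property
    def cells(self) -> list[tuple[int, float]]:
        return [(n, w) for n in self.n_i_values for w in self.w_ie_values]


@dataclass
class ExperimentConfig:
    """One fully specified simulation condition."""

    topology_kind: str                 # 'two-group' | 'ring'
    group_specs: list[GroupSpec]
    schedule: SimulationSchedule
    plasticity: PlasticityParameters = field(default_factory=PlasticityParameters)
    stimulated_group: int = 0
    scale: float = 1.0
    name: str = ""

    def topology(self):
        return two_group_topology() if self.topology_kind == "two-group" else ring_topology()


def _scaled_schedule(scale: float) -> SimulationSchedule:
    if scale >= 1.0:
        return SimulationSchedule.paper()
    return SimulationSchedule.scaled()


def _group(n_i: int, w_ie: float, scale: float, imbalanced: bool) -> GroupSpec:
    return GroupSpec(
        n_excitatory=max(1, round(800 * scale)),
        n_inhibitory=max(1, round(n_i * scale)),
        w_ie=w_ie,
        imbalanced=imbalanced,
    )


def two_group_config(
    n_i: int = 200, w_ie: float = 0.025, scale: float = 0.125,
    schedule: SimulationSchedule | None = None, stimulated_group: int = 0,
) -> ExperimentConfig:
    """Two-group condition: group 0 imbalanced at (n_i, w_ie), group 1 baseline."""
    return ExperimentConfig(
        topology_kind="two-group",
        group_specs=[
            _group(n_i, w_ie, scale, imbalanced=(n_i, w_ie) != BASELINE),
            _group(*BASELINE, scale, imbalanced=False),
        ],
        schedule=schedule or _scaled_schedule(scale),
        stimulated_group=stimulated_group,
        scale=scale,
        name=f"two-group N_I={n_i} W_IE={w_ie}",
    )


def ring_config(
    preset: str = "B", stimulated_group: int = 0, scale: float = 0.125,
    schedule: SimulationSchedule | None = None,
) -> ExperimentConfig:
    """Ten-group ring: group 0 takes the preset parameters, others baseline."""
    if preset not in PRESETS:
        raise ValueError(f"preset must be one of {sorted(PRESETS)}")
    if not 0 <= stimulated_group < 10:
        raise ValueError("stimulated_group must be in 0..9")
    n_i, w_ie = PRESETS[preset]
    specs = [_group(n_i, w_ie, scale, imbalanced=preset != "B")]
    specs += [_group(*BASELINE, scale, imbalanced=False) for _ in range(9)]
    return ExperimentConfig(
        topology_kind="ring",
        group_specs=specs,
        schedule=schedule or _scaled_schedule(scale),
        stimulated_group=stimulated_group,
        scale=scale,
        name=f"ring {preset}-E/I stim={stimulated_group}",
    )


def derive_seeds(master_seed: int, n: int, stream: int = 0) -> list[int]:
    """Counter-based child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream,))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def build_inputs(config: ExperimentConfig, table, rng: np.random.Generator) -> InputEvents:
    """Background input to every neuron; external input to the stimulated group."""
    sched = config.schedule
    bg_spec = PoissonInputSpec(
        rate_hz=BACKGROUND_RATE_HZ, weight=BACKGROUND_WEIGHT,
        targets=tuple(range(table.n_neurons)),
    )
    bg = generate_inputs(bg_spec, sched.total_s, sched.dt_ms, rng)
    ext_targets = table.neurons_of(config.stimulated_group, excitatory=True)
    ext_spec = PoissonInputSpec(
        rate_hz=external_input_rate, weight=EXTERNAL_WEIGHT,
        targets=tuple(int(i) for i in ext_targets),
        t_start_s=sched.input_window_s[0], t_stop_s=sched.input_window_s[1],
    )
    ext = generate_inputs(ext_spec, sched.total_s, sched.dt_ms, rng, external=True)
    return merge_events(bg, ext)


def run_single(
    config: ExperimentConfig,
    seed: int,
    analyses: tuple[str, ...] = ("weights", "rates", "mse", "info"),
    mse_params: MSEParameters | None = None,
    keep_recording: bool = False,
    plastic_enabled: bool = True,
) -> dict:
    """One seeded run of a condition; returns a flat summary dict."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    table = build_network(config.topology(), config.group_specs, rng,
                          dt=config.schedule.dt_ms)
    events = build_inputs(config, table, rng)
    rec = run_simulation(
        table, config.schedule, events, config.plasticity,
        plastic_enabled=plastic_enabled,
        metadata={"seed": seed, "condition": config.name},
    )
    summary: dict = {"seed": seed, "condition": config.name, "scale": config.scale}
    n_groups = table.n_groups

    if "weights" in analyses:
        wmat = summarize_weights(table, rec.final_weights)
        for i in range(n_groups):
            summary[f"w_intra_g{i}"] = wmat[i, i]
            for j in range(n_groups):
                if i != j and np.isfinite(wmat[i, j]):
                    summary[f"w_inter_g{i}_g{j}"] = wmat[i, j]
        exc = ~table.inhibitory
        summary["w_exc_mean"] = float(rec.final_weights[exc].mean())

    window = config.schedule.complexity_window_s
    if "rates" in analyses:
        rates = compute_firing_rates(rec, window)
        for (gi, label), r in rates.items():
            summary[f"rate_{label[:3]}_g{gi}"] = r
        summary["rate_exc_mean"] = float(
            np.mean([v for (g, lab), v in rates.items() if lab == "excitatory"])
        )
        summary["cv_isi_exc"] = isi_cv(rec, window)

    if "mse" in analyses:
        params = mse_params or MSEParameters()
        indices = []
        for gi in range(n_groups):
            lap = rec.lap_series(gi, window)
            lap_ms = downsample_lap(lap, target_interval_ms=1.0)
            res = mse_curve(lap_ms.values, params)
            summary[f"mse_index_g{gi}"] = res.complexity_index
            summary[f"mse_valid_scales_g{gi}"] = int(res.valid.sum())
            indices.append(res.complexity_index)
        summary["mse_index_mean"] = float(np.mean(indices))

    if "info" in analyses:
        s0, s1 = config.schedule.window_steps(config.schedule.input_window_s)
        drive = external_drive_signal(events.external_steps, s0, s1 - s0)
        info = information_pipeline(
            rec, drive, config.stimulated_group,
            seed=np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,))),
        )
        for gi, v in info.mi.items():
            summary[f"mi_g{gi}"] = v
        summary["mi_mean"] = float(np.mean(list(info.mi.values())))
        for (si, gj), v in info.te.items():
            summary[f"te_g{si}_g{gj}"] = v
        if info.te:
            summary["te_mean"] = float(np.mean(list(info.te.values())))

    if keep_recording:
        summary["recording"] = rec
    return summary


def run_condition(
    config: ExperimentConfig, seeds, analyses=("weights", "rates", "mse", "info"),
) -> pd.DataFrame:
    """Run a condition once per seed; failed runs are recorded, not averaged."""
    rows, failures = [], []
    for s in seeds:
        try:
            rows.append(run_single(config, s, analyses=analyses))
        except Exception as exc:  # noqa: BLE001 - partial failure bookkeeping
            failures.append({"seed": s, "condition": config.name, "error": str(exc)})
    df = pd.DataFrame(rows)
    if failures:
        df.attrs["failures"] = failures
        import warnings

        warnings.warn(f"{len(failures)} run(s) failed and were excluded", stacklevel=2)
    return df


def run_condition_grid(
    cells, master_seed: int, runs_per_condition: int = 10, scale: float = 0.125,
    analyses=("weights", "rates", "mse"),
) -> pd.DataFrame:
    """Run each (N_I, W_IE) cell with its own derived seed stream."""
    frames = []
    for idx, (n_i, w_ie) in enumerate(cells):
        config = two_group_config(n_i, w_ie, scale=scale)
        seeds = derive_seeds(master_seed, runs_per_condition, stream=idx)
        df = run_condition(config, seeds, analyses=analyses)
        df["n_i"] = n_i
        df["w_ie"] = w_ie
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples degenerate with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney_one_sided(sample_a, sample_b, alternative: str = "greater") -> float:
    """One-sided Mann-Whitney p-value for sample_a vs sample_b."""
    return float(stats.mannwhitneyu(sample_a, sample_b, alternative=alternative).pvalue)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def aggregate_and_report(
    results: pd.DataFrame,
    group_cols=("n_i", "w_ie"),
    baseline: tuple = BASELINE,
    out_csv=None,
    out_json=None,
) -> pd.DataFrame:
    """Condition means, SDs (n-1 denominator) and Welch p-values vs baseline.

    Pure given its inputs (no randomness).  Writes identical numbers to CSV
    and JSON when paths are given.
    """
    group_cols = list(group_cols)
    metric_cols = [
        c for c in results.columns
        if c not in group_cols + ["seed", "condition", "scale", "recording"]
        and np.issubdtype(results[c].dtype, np.number)
    ]
    have_baseline = (
        all(c in results.columns for c in group_cols)
        and ((results[group_cols[0]] == baseline[0]) & (results[group_cols[1]] == baseline[1])).any()
        and len(results.groupby(group_cols)) > 1
    )
    rows = []
    for key, sub in results.groupby(group_cols):
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row["n_runs"] = len(sub)
        for m in metric_cols:
            row[f"{m}_mean"] = sub[m].mean()
            row[f"{m}_sd"] = sub[m].std(ddof=1)
        if have_baseline and tuple(row[c] for c in group_cols) != baseline:
            base = results[
                (results[group_cols[0]] == baseline[0]) & (results[group_cols[1]] == baseline[1])
            ]
            for m in metric_cols:
                if base[m].notna().all() and sub[m].notna().all():
                    try:
                        _, _, p = welch_t_test(sub[m], base[m])
                    except ValueError:
                        continue
                    row[f"{m}_p"] = p
                    row[f"{m}_stars"] = significance_stars(p)
        rows.append(row)
    report = pd.DataFrame(rows)
    if out_csv is not None:
        report.to_csv(out_csv, index=False)
    if out_json is not None:
        with open(out_json, "w") as f:
            json.dump(json.loads(report.to_json(orient="records")), f, indent=2)
    return report
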