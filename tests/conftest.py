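import numpy as np
import pandas as pd
import pytest

from eibalance.engine import SimulationSchedule
from eibalance.experiments import derive_seeds, run_condition, two_group_config

#: master seed for every stochastic test in the suite
MASTER_SEED = 20260929


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def replication_batch():
    """Desk-scale two-group runs: 10 seeds each of the weak-inhibition (H-E/I)
    and baseline (B-E/I) conditions, with the full analysis chain.

    Session-scoped because each run integrates 72 s of network time; the
    weight-bound and directional-replication checks share it.
    """
    out = {}
    for name, (n_i, w_ie), stream in (("B", (200, 0.025), 1), ("H", (100, 0.0125), 0)):
        cfg = two_group_config(n_i, w_ie, scale=0.125)
        seeds = derive_seeds(MASTER_SEED, 10, stream=stream)
        df = run_condition(cfg, seeds)
        assert "failures" not in df.attrs, df.attrs.get("failures")
        assert len(df) == 10
        out[name] = df
    return out


@pytest.fixture(scope="session")
def tiny_schedule():
    """A seconds-long schedule for fast engine-contract tests."""
    return SimulationSchedule.scaled(
        stdp_duration_s=1.0, warmup_s=0.2, analysis_s=0.5, input_s=0.5
    )
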