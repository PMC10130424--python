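"""Multi-group network construction.

Networks consist of identical neuron groups, each with ``n_excitatory``
regular-spiking and ``n_inhibitory`` fast-spiking neurons.  Every excitatory
neuron sends 70 synapses to distinct random neurons of its own group and 30 to
random neurons of adjacent groups (the ~7:3 local/global ratio of cortical
pyramidal cells); inhibitory neurons send 100 synapses within their group
only.  Excitatory synapses are plastic with initial weights drawn uniformly
from [0, w_init_max]; inhibitory synapses carry the fixed weights W_IE (onto
excitatory targets) or W_II (onto inhibitory targets).  Conduction delays are
uniform — 2-4 ms for intra-group excitatory, 4-10 ms for inter-group
excitatory, 1-3 ms for inhibitory synapses — and stored as integer step counts.

Two topologies are supported: two mutually connected groups, and a ring of ten
groups where each group connects to its four nearest neighbours (positions
±1, ±2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised for inconsistent network specifications."""


@dataclass(frozen=True)
class GroupSpec:
    """Size and inhibitory coupling of one neuron group."""

    n_excitatory: int = 800
    n_inhibitory: int = 200
    w_ie: float = 0.025
    w_ii: float = 0.013
    imbalanced: bool = False

    def __post_init__(self) -> None:
        if self.n_excitatory <= 0 or self.n_inhibitory <= 0:
            raise ConfigurationError("group sizes must be positive")
        if self.w_ie < 0 or self.w_ii < 0:
            raise ConfigurationError("inhibitory weights must be non-negative")


@dataclass(frozen=True)
class NetworkTopology:
    """Group count plus symmetric inter-group adjacency."""

    n_groups: int
    adjacency: tuple[tuple[int, ...], ...]  # adjacency[g] = neighbour groups of g

    def __post_init__(self) -> None:
        for g, nbrs in enumerate(self.adjacency):
            for h in nbrs:
                if g not in self.adjacency[h]:
                    raise ConfigurationError("adjacency must be symmetric")
                if h == g:
                    raise ConfigurationError("groups are not adjacent to themselves")


def two_group_topology() -> NetworkTopology:
    return NetworkTopology(n_groups=2, adjacency=((1,), (0,)))


def ring_topology(n_groups: int = 10, reach: int = 2) -> NetworkTopology:
    """Ring of groups, each adjacent to ``reach`` neighbours on either side."""
    adj = []
    for g in range(n_groups):
        nbrs = sorted(
            {(g + off) % n_groups for off in range(-reach, reach + 1) if off != 0}
        )
        adj.append(tuple(nbrs))
    return NetworkTopology(n_groups=n_groups, adjacency=tuple(adj))


# connectivity defaults (per-neuron out-degrees)
N_INTRA_EXC = 70
N_INTER_EXC = 30
N_INTRA_INH = 100
W_INIT_MAX = 0.04

# delay ranges, ms
DELAY_EXC_INTRA = (2.0, 4.0)
DELAY_EXC_INTER = (4.0, 10.0)
DELAY_INH = (1.0, 3.0)


@dataclass
class ConnectionTable:
    """Flat arrays describing every directed synapse, plus group membership.

    ``inhibitory`` marks GABAergic synapses (drive the GABA channel);
    excitatory synapses drive AMPA+NMDA.  ``plastic`` marks synapses governed
    by the triplet STDP rule (all excitatory ones).
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_steps: np.ndarray
    inhibitory: np.ndarray
    plastic: np.ndarray
    group_of: np.ndarray          # group index per neuron
    is_excitatory: np.ndarray     # bool per neuron
    metadata: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.group_of.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.pre.shape[0]

    @property
    def n_groups(self) -> int:
        return int(self.group_of.max()) + 1

    def neurons_of(self, group: int, excitatory: bool | None = None) -> np.ndarray:
        mask = self.group_of == group
        if excitatory is not None:
            mask &= self.is_excitatory == excitatory
        return np.flatnonzero(mask)

    def validate(self) -> None:
        """Check structural invariants; raises ConfigurationError on violation."""
        if np.any(self.pre == self.post):
            raise ConfigurationError("self-connections present")
        key = self.pre.astype(np.int64) * self.n_neurons + self.post
        if np.unique(key).size != key.size:
            raise ConfigurationError("duplicate (pre, post) pairs present")
        if np.any(self.delay_steps < 1):
            raise ConfigurationError("delays must be at least one step")
        exc = ~self.inhibitory
        if not np.all(self.plastic[exc]):
            raise ConfigurationError("all excitatory synapses must be plastic")
        if np.any(self.plastic[self.inhibitory]):
            raise ConfigurationError("inhibitory synapses must be static")
        if np.any(self.weight[exc] < 0) or np.any(self.weight[exc] > W_INIT_MAX):
            raise ConfigurationError("excitatory weights outside [0, 0.04]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "weight": self.weight,
                "delay_steps": self.delay_steps,
                "inhibitory": self.inhibitory,
                "plastic": self.plastic,
            }
        )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("pre", "post", "weight", "delay_steps", "inhibitory",
                         "plastic", "group_of", "is_excitatory"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load_hdf5(cls, path) -> "ConnectionTable":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {
                name: f[name][...]
                for name in ("pre", "post", "weight", "delay_steps", "inhibitory",
                             "plastic", "group_of", "is_excitatory")
            }
        kw["inhibitory"] = kw["inhibitory"].astype(bool)
        kw["plastic"] = kw["plastic"].astype(bool)
        kw["is_excitatory"] = kw["is_excitatory"].astype(bool)
        return cls(**kw)


def _sample_targets(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    if pool.size < k:
        raise ConfigurationError(
            f"cannot draw {k} distinct targets from a pool of {pool.size} neurons"
        )
    return rng.choice(pool, size=k, replace=False)


def build_network(
    topology: NetworkTopology,
    group_specs: list[GroupSpec],
    seed: int | np.random.Generator,
    n_intra_exc: int = N_INTRA_EXC,
    n_inter_exc: int = N_INTER_EXC,
    n_intra_inh: int = N_INTRA_INH,
    w_init_max: float = W_INIT_MAX,
    dt: float = 0.05,
) -> ConnectionTable:
    """Sample a network realization; delays are filled in by the same call.

    Targets are drawn without replacement, uniformly over all neurons of the
    candidate group(s) excluding the source itself.  The 30 inter-group
    targets of an excitatory neuron are pooled uniformly over all adjacent
    groups' neurons.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(group_specs) != topology.n_groups:
        raise ConfigurationError("one GroupSpec required per group")

    group_of = []
    is_exc = []
    for g, spec in enumerate(group_specs):
        group_of.extend([g] * (spec.n_excitatory + spec.n_inhibitory))
        is_exc.extend([True] * spec.n_excitatory + [False] * spec.n_inhibitory)
    group_of = np.asarray(group_of, dtype=np.int32)
    is_exc = np.asarray(is_exc, dtype=bool)
    n_neurons = group_of.shape[0]
    all_ids = np.arange(n_neurons, dtype=np.int32)

    members = [all_ids[group_of == g] for g in range(topology.n_groups)]
    pools_inter = [
        np.concatenate([members[h] for h in topology.adjacency[g]])
        for g in range(topology.n_groups)
    ]

    pre_l, post_l, w_l, inh_l, plast_l, intra_l = [], [], [], [], [], []
    for g, spec in enumerate(group_specs):
        for nid in members[g]:
            own = members[g][members[g] != nid]
            if is_exc[nid]:
                intra = _sample_targets(rng, own, n_intra_exc)
                inter = _sample_targets(rng, pools_inter[g], n_inter_exc)
                tgts = np.concatenate([intra, inter])
                pre_l.append(np.full(tgts.size, nid, dtype=np.int32))
                post_l.append(tgts.astype(np.int32))
                w_l.append(rng.uniform(0.0, w_init_max, size=tgts.size))
                inh_l.append(np.zeros(tgts.size, dtype=bool))
                plast_l.append(np.ones(tgts.size, dtype=bool))
                intra_l.append(
                    np.concatenate([np.ones(intra.size, bool), np.zeros(inter.size, bool)])
                )
            else:
                tgts = _sample_targets(rng, own, n_intra_inh)
                pre_l.append(np.full(tgts.size, nid, dtype=np.int32))
                post_l.append(tgts.astype(np.int32))
                w_l.append(np.where(is_exc[tgts], spec.w_ie, spec.w_ii))
                inh_l.append(np.ones(tgts.size, dtype=bool))
                plast_l.append(np.zeros(tgts.size, dtype=bool))
                intra_l.append(np.ones(tgts.size, dtype=bool))

    table = ConnectionTable(
        pre=np.concatenate(pre_l),
        post=np.concatenate(post_l),
        weight=np.concatenate(w_l),
        delay_steps=np.zeros(sum(a.size for a in pre_l), dtype=np.int32),
        inhibitory=np.concatenate(inh_l),
        plastic=np.concatenate(plast_l),
        group_of=group_of,
        is_excitatory=is_exc,
        metadata={
            "n_intra_exc": n_intra_exc,
            "n_inter_exc": n_inter_exc,
            "n_intra_inh": n_intra_inh,
            "inter_sampling": "pooled-uniform over adjacent groups",
        },
    )
    table.metadata["intra_mask"] = np.concatenate(intra_l)
    sample_delays(table, dt=dt, rng=rng)
    return table


def sample_delays(
    table: ConnectionTable,
    dt: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> ConnectionTable:
    """Draw conduction delays in ms and convert to integer steps (min 1).

    Continuous uniform samples are rounded to the nearest step.  Modifies the
    table in place and returns it.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    intra = table.metadata.get("intra_mask")
    if intra is None:
        intra = table.group_of[table.pre] == table.group_of[table.post]
    n = table.n_synapses
    ms = np.empty(n)
    m_inh = table.inhibitory
    m_intra_exc = ~m_inh & intra
    m_inter_exc = ~m_inh & ~intra
    ms[m_intra_exc] = rng.uniform(*DELAY_EXC_INTRA, size=int(m_intra_exc.sum()))
    ms[m_inter_exc] = rng.uniform(*DELAY_EXC_INTER, size=int(m_inter_exc.sum()))
    ms[m_inh] = rng.uniform(*DELAY_INH, size=int(m_inh.sum()))
    table.delay_steps = np.maximum(1, np.rint(ms / dt)).astype(np.int32)
    return table


def summarize_weights(
    table: ConnectionTable, weights: np.ndarray | None = None
) -> np.ndarray:
    """Mean excitatory weight per (source group, target group).

    Returns a (G, G) matrix; diagonal entries are the intra-group means.
    Entries with no excitatory synapses are NaN (flagged undefined, never
    silently zero).
    """
    w = table.weight if weights is None else weights
    g = table.n_groups
    out = np.full((g, g), np.nan)
    exc = ~table.inhibitory
    src = table.group_of[table.pre]
    tgt = table.group_of[table.post]
    for i in range(g):
        for j in range(g):
            m = exc & (src == i) & (tgt == j)
            if m.any():
                out[i, j] = w[m].mean()
    return out


def scaled_group_spec(
    n_i: int = 200, w_ie: float = 0.025, scale: float = 1.0, w_ii: float = 0.013,
    imbalanced: bool = False,
) -> GroupSpec:
    """GroupSpec with neuron counts scaled by ``scale`` (weights untouched)."""
    return GroupSpec(
        n_excitatory=max(1, round(800 * scale)),
        n_inhibitory=max(1, round(n_i * scale)),
        w_ie=w_ie,
        w_ii=w_ii,
        imbalanced=imbalanced,
    )
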