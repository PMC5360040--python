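"""In-silico benchmark network and time-course data generation.

Builds random gene regulatory networks whose in-degree distribution follows a
truncated discrete power law, assigns Hill-kinetics parameters within the
benchmark bounds, and simulates two independent perturbation experiments
(distinct random subsets of externally stimulated genes) with the delayed
network model.  Defaults reproduce the standard benchmark conditions: 1000
genes at ~3.7 incoming edges per gene (~3700 edges), binding constants
K in [0.25, 9.75], stimulus strength e in [1, 21], delay tau = 1 h, Hill
n = 2, initial expression 1, and 12 equally spaced timepoints over [0, 11] h
with 250 and 200 stimulated genes in experiments 1 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .model import KineticParameters, ModelError, TimeCourseDataset, simulate_network_dde

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"


class ConfigError(ValueError):
    """Invalid generation configuration."""


@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    role: str
    K: float = float("nan")

    def __post_init__(self):
        if self.role not in (ACTIVATOR, INHIBITOR):
            raise ConfigError(f"edge role must be activator/inhibitor, got {self.role!r}")
        if self.source == self.target:
            raise ConfigError(f"self-edge on gene {self.source}")


@dataclass(frozen=True)
class NetworkTopology:
    """Signed directed edge list with per-edge binding constants."""

    n_genes: int
    edges: tuple[Edge, ...]

    def __post_init__(self):
        pairs = [(e.source, e.target) for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ConfigError("duplicate (source, target) edge")
        for e in self.edges:
            if not (0 <= e.source < self.n_genes and 0 <= e.target < self.n_genes):
                raise ConfigError(f"edge {e} outside gene universe of size {self.n_genes}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def regulators_of(self, target: int) -> tuple[tuple[tuple[int, float], ...],
                                                  tuple[tuple[int, float], ...]]:
        act = tuple((e.source, e.K) for e in self.edges if e.target == target and e.role == ACTIVATOR)
        inh = tuple((e.source, e.K) for e in self.edges if e.target == target and e.role == INHIBITOR)
        return act, inh

    def edge_set(self) -> set[tuple[int, int, str]]:
        return {(e.source, e.target, e.role) for e in self.edges}

    def edge_arrays(self):
        """(act_src, act_tgt, act_K, inh_src, inh_tgt, inh_K) index arrays."""
        act = [(e.source, e.target, e.K) for e in self.edges if e.role == ACTIVATOR]
        inh = [(e.source, e.target, e.K) for e in self.edges if e.role == INHIBITOR]

        def unpack(rows):
            if not rows:
                return (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0))
            s, t, k = zip(*rows)
            return np.asarray(s, dtype=int), np.asarray(t, dtype=int), np.asarray(k)

        return unpack(act) + unpack(inh)


@dataclass(frozen=True)
class StimulusAssignment:
    """Which genes receive an external stimulus e > 0 in one experiment."""

    stimulated: frozenset[int]
    e_values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "stimulated", frozenset(self.stimulated))
        if set(self.e_values) != set(self.stimulated):
            raise ConfigError("e_values keys must equal the stimulated set")


@dataclass(frozen=True)
class GenerationConfig:
    n_genes: int = 1000
    mean_in_degree: float = 3.7
    k_min: int = 1
    k_max: int = 20
    k_bounds: tuple[float, float] = (0.25, 9.75)
    e_bounds: tuple[float, float] = (1.0, 21.0)
    r0_bounds: tuple[float, float] = (0.5, 2.0)
    d_bounds: tuple[float, float] = (0.5, 2.0)
    p_act: float = 0.5
    tau: float = 1.0
    hill_n: float = 2.0
    x0: float = 1.0
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(12))
    stimulated_counts: tuple[int, ...] = (250, 200)

    def __post_init__(self):
        for lo, hi in (self.k_bounds, self.e_bounds, self.r0_bounds, self.d_bounds):
            if not lo <= hi:
                raise ConfigError(f"bounds must be ordered, got ({lo}, {hi})")
        if not 1 <= self.k_min <= self.k_max <= self.n_genes - 1:
            raise ConfigError("need 1 <= k_min <= k_max <= n_genes - 1")
        if not self.k_min <= self.mean_in_degree <= self.k_max:
            raise ConfigError("mean in-degree outside [k_min, k_max]")
        if any(c > self.n_genes for c in self.stimulated_counts):
            raise ConfigError("cannot stimulate more genes than exist")
        if not 0 <= self.p_act <= 1:
            raise ConfigError("p_act must be a probability")


def _truncated_powerlaw_mean(gamma: float, k: np.ndarray) -> float:
    w = k.astype(float) ** (-gamma)
    return float((k * w).sum() / w.sum())


def powerlaw_pmf(config: GenerationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the truncated in-degree power law P(k) ~ k^-gamma.

    The exponent gamma is calibrated numerically so that the distribution's
    mean equals ``config.mean_in_degree``.
    """
    k = np.arange(config.k_min, config.k_max + 1)
    if k.size == 1:
        return k, np.ones(1)
    gamma = brentq(lambda g: _truncated_powerlaw_mean(g, k) - config.mean_in_degree, -50.0, 50.0)
    w = k.astype(float) ** (-gamma)
    return k, w / w.sum()


def sample_in_degrees(config: GenerationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene number of incoming edges, one draw per gene."""
    k, pmf = powerlaw_pmf(config)
    return rng.choice(k, size=config.n_genes, p=pmf)


def sample_topology(degrees: Sequence[int], config: GenerationConfig,
                    rng: np.random.Generator) -> NetworkTopology:
    """Wire each gene's regulators uniformly at random (no self/duplicate edges).

    Each edge is independently an activator with probability ``p_act``.
    Binding constants are filled in by :func:`sample_parameters`.
    """
    n = config.n_genes
    degrees = np.asarray(degrees, dtype=int)
    if degrees.size != n or np.any(degrees > n - 1) or np.any(degrees < 0):
        raise ConfigError("invalid in-degree vector")
    edges = []
    for target, k in enumerate(degrees):
        pool = np.delete(np.arange(n), target)
        sources = rng.choice(pool, size=k, replace=False)
        roles = np.where(rng.random(k) < config.p_act, ACTIVATOR, INHIBITOR)
        edges.extend(Edge(int(s), target, str(r)) for s, r in zip(sources, roles))
    return NetworkTopology(n_genes=n, edges=tuple(edges))


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def sample_parameters(topology: NetworkTopology, config: GenerationConfig,
                      rng: np.random.Generator) -> tuple[NetworkTopology, list[KineticParameters]]:
    """Draw binding constants and per-gene kinetics.

    K ~ Uniform(0.25, 9.75) per edge; r0 and d log-uniform within their
    configured ranges per gene; e is zero here (stimuli set it per experiment);
    n and tau come from the config.
    """
    ks = rng.uniform(*config.k_bounds, size=topology.n_edges)
    edges = tuple(replace(e, K=float(k)) for e, k in zip(topology.edges, ks))
    r0 = _loguniform(rng, *config.r0_bounds, size=topology.n_genes)
    d = _loguniform(rng, *config.d_bounds, size=topology.n_genes)
    params = [
        KineticParameters(r0=float(a), d=float(b), e=0.0, n=config.hill_n, tau=config.tau)
        for a, b in zip(r0, d)
    ]
    return NetworkTopology(topology.n_genes, edges), params


def assign_stimuli(n_genes: int, count: int, e_bounds: tuple[float, float],
                   rng: np.random.Generator) -> StimulusAssignment:
    """Pick ``count`` distinct genes at random and draw their stimulus strength."""
    if count > n_genes:
        raise ConfigError(f"cannot stimulate {count} of {n_genes} genes")
    genes = rng.choice(n_genes, size=count, replace=False)
    es = rng.uniform(*e_bounds, size=count)
    return StimulusAssignment(frozenset(int(g) for g in genes),
                              {int(g): float(v) for g, v in zip(genes, es)})


@dataclass(frozen=True)
class GeneratedBenchmark:
    config: GenerationConfig
    seed: int
    topology: NetworkTopology
    params: tuple[KineticParameters, ...]
    stimuli: tuple[StimulusAssignment, ...]
    datasets: tuple[TimeCourseDataset, ...]


def generate_topology(config: GenerationConfig, seed: int) -> NetworkTopology:
    """Topology plus binding constants only (no simulation)."""
    ss = np.random.SeedSequence(seed)
    rng_deg, rng_top, rng_par = (np.random.default_rng(s) for s in ss.spawn(3))
    degrees = sample_in_degrees(config, rng_deg)
    topo = sample_topology(degrees, config, rng_top)
    topo, _ = sample_parameters(topo, config, rng_par)
    return topo


def generate_dataset(config: GenerationConfig, seed: int) -> GeneratedBenchmark:
    """Full benchmark: one network, one parameter set, one dataset per experiment.

    Experiments share the topology and kinetics and differ only in which genes
    are externally stimulated.  Fully reproducible from (config, seed).
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 + len(config.stimulated_counts))
    rng_deg, rng_top, rng_par = (np.random.default_rng(s) for s in children[:3])
    degrees = sample_in_degrees(config, rng_deg)
    topo = sample_topology(degrees, config, rng_top)
    topo, params = sample_parameters(topo, config, rng_par)

    timepoints = np.asarray(config.timepoints)
    x0 = np.full(config.n_genes, config.x0)
    stimuli, datasets = [], []
    for i, (count, child) in enumerate(zip(config.stimulated_counts, children[3:]), start=1):
        stim = assign_stimuli(config.n_genes, count, config.e_bounds, np.random.default_rng(child))
        ds = simulate_network_dde(topo, params, stim, timepoints, x0=x0)
        ds.experiment_id = f"exp{i}"
        stimuli.append(stim)
        datasets.append(ds)
    return GeneratedBenchmark(config=config, seed=seed, topology=topo,
                              params=tuple(params), stimuli=tuple(stimuli),
                              datasets=tuple(datasets))
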