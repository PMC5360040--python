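"""Shared fixtures and independent numerical oracles.

The oracles here deliberately re-derive the model by literal transcription of
the kinetics (per-gene Python loops, fixed-step integration) so they share no
code path with the package's solvers.
"""

from __future__ import annotations

import numpy as np
import pytest

from hillsemble.model import KineticParameters, TimeCourseDataset, simulate_network_dde
from hillsemble.netgen import Edge, NetworkTopology


def hill_rate_literal(r0, e, n, x_delayed, activators, inhibitors):
    """Literal transcription-rate formula for one gene (independent oracle)."""
    a = sum(x_delayed[i] / k for i, k in activators)
    i_ = sum(x_delayed[i] / k for i, k in inhibitors)
    return r0 * (a ** n + e) / (1.0 + i_ ** n + a ** n + e)


def euler_dde_oracle(topology: NetworkTopology, params, stimuli, timepoints,
                     dt: float = 1e-3, x0: float = 1.0) -> np.ndarray:
    """Fixed-step method-of-steps integration of the delayed network (Heun).

    Constant history x(t) = x0 for t <= t0; delayed state read from the stored
    step at exactly t - tau (tau is an integer multiple of dt).  A second-order
    explicit step is used so the oracle's own discretization error (~dt^2)
    stays well below the comparison tolerance.  Returns genes x timepoints.
    """
    n = topology.n_genes
    tau = params[0].tau
    regs = [topology.regulators_of(g) for g in range(n)]
    r0 = np.array([p.r0 for p in params])
    d = np.array([p.d for p in params])
    e = np.array([p.e for p in params])
    hill = params[0].n
    if stimuli is not None:
        for g, ev in stimuli.e_values.items():
            e[g] = ev
    t0, t_end = float(timepoints[0]), float(timepoints[-1])
    n_steps = int(round((t_end - t0) / dt))
    lag = int(round(tau / dt))
    path = np.empty((n_steps + 1, n))
    path[0] = x0
    def rate_at(xd: np.ndarray) -> np.ndarray:
        return np.array([
            hill_rate_literal(r0[g], e[g], hill, xd, regs[g][0], regs[g][1])
            for g in range(n)
        ])

    hist = np.full(n, float(x0))
    for k in range(n_steps):
        xd1 = path[k - lag] if k - lag >= 0 else hist
        xd2 = path[k + 1 - lag] if k + 1 - lag >= 0 else hist
        f1 = rate_at(xd1) - d * path[k]
        xp = path[k] + dt * f1
        f2 = rate_at(xd2) - d * xp
        path[k + 1] = path[k] + dt / 2 * (f1 + f2)
    idx = np.round((np.asarray(timepoints) - t0) / dt).astype(int)
    return path[idx].T


def random_small_network(rng: np.random.Generator, n: int = 10,
                         stimulated: int = 3):
    """A random n-gene instance with benchmark-style parameter ranges."""
    from hillsemble.netgen import StimulusAssignment

    edges, seen = [], set()
    for target in range(n):
        k = int(rng.integers(1, 4))
        pool = [g for g in range(n) if g != target]
        for s in rng.choice(pool, size=k, replace=False):
            if (int(s), target) not in seen:
                seen.add((int(s), target))
                role = "activator" if rng.random() < 0.5 else "inhibitor"
                edges.append(Edge(int(s), target, role, float(rng.uniform(0.25, 9.75))))
    topo = NetworkTopology(n, tuple(edges))
    params = [
        KineticParameters(r0=float(np.exp(rng.uniform(np.log(0.5), np.log(2)))),
                          d=float(np.exp(rng.uniform(np.log(0.5), np.log(2)))),
                          e=0.0)
        for _ in range(n)
    ]
    stim_genes = rng.choice(n, size=stimulated, replace=False)
    ev = {int(g): float(rng.uniform(1, 21)) for g in stim_genes}
    return topo, params, StimulusAssignment(frozenset(ev), ev)


def identifiable_ten_gene_fixture() -> tuple[NetworkTopology, TimeCourseDataset]:
    """Ten-gene network whose target (gene 0) has an identifiable 2-activator /
    2-inhibitor regulator set.

    Genes 1 and 3 form a delayed negative-feedback oscillator (two distinct
    phases), gene 2 carries a lagged mixed waveform, gene 4 a slow pure decay,
    and genes 5-9 sit exactly at steady state.  Informative signal shapes
    therefore exist only in the true regulators; constant decoys are
    absorbed by the free constitutive term of any trial model.
    """
    kp = KineticParameters
    edges = (
        Edge(1, 3, "activator", 0.4), Edge(3, 1, "inhibitor", 0.4),
        Edge(1, 2, "activator", 0.5), Edge(3, 2, "inhibitor", 1.5),
        Edge(1, 0, "activator", 0.6), Edge(2, 0, "activator", 1.0),
        Edge(3, 0, "inhibitor", 1.0), Edge(4, 0, "inhibitor", 0.7),
    )
    topo = NetworkTopology(10, edges)
    params = [
        kp(r0=2.5, d=2.0, e=0.0),
        kp(r0=3.0, d=1.0, e=5.0),
        kp(r0=1.6, d=0.8, e=0.0),
        kp(r0=3.0, d=1.0, e=0.0),
        kp(r0=1.0, d=0.25, e=0.0),
        kp(r0=1.2, d=0.96, e=4.0),
        kp(r0=0.8, d=8.0 / 15.0, e=2.0),
        kp(r0=2.0, d=1.8, e=9.0),
        kp(r0=0.6, d=0.3, e=1.0),
        kp(r0=1.5, d=1.4, e=14.0),
    ]
    ds = simulate_network_dde(topo, params, None, np.arange(12.0))
    ds.experiment_id = "fixture"
    return topo, ds


@pytest.fixture(scope="session")
def ten_gene_fixture():
    return identifiable_ten_gene_fixture()
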