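"""Per-gene ensemble subnetwork search.

The network inverse problem is decomposed into one independent problem per
target gene: sample many random candidate regulator sets ("trial
subnetworks"), fit each candidate's kinetic parameters to the target's time
course by bounded nonlinear least squares — regulator trajectories are
spline interpolants of the measured data, evaluated with the transcription
delay — and keep the candidates whose normalized residual falls below an
acceptance threshold.  The relative frequency with which an edge appears in
the accepted ensemble is the downstream likelihood score for that edge.

All randomness is derived per (master seed, gene, trial index), so results do
not depend on batch size, execution order, or worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import least_squares

from .model import (
    IntegrationError,
    ModelError,
    RegulatorSignal,
    TimeCourseDataset,
    integrate_linear_production,
    refine_timegrid,
)

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"


@dataclass(frozen=True)
class CandidateSubnetwork:
    """Candidate regulator index sets for one target gene."""

    target: int
    activators: tuple[int, ...]
    inhibitors: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "activators", tuple(int(g) for g in self.activators))
        object.__setattr__(self, "inhibitors", tuple(int(g) for g in self.inhibitors))
        a, b = set(self.activators), set(self.inhibitors)
        if len(a) != len(self.activators) or len(b) != len(self.inhibitors) or a & b:
            raise ModelError("candidate role sets must be disjoint and duplicate-free")
        if self.target in a | b:
            raise ModelError("candidate must not contain the target")
        if not self.activators and not self.inhibitors:
            raise ModelError("candidate must contain at least one regulator")

    @property
    def size(self) -> int:
        return len(self.activators) + len(self.inhibitors)


@dataclass
class FitResult:
    candidate: CandidateSubnetwork
    k_act: tuple[float, ...]
    k_inh: tuple[float, ...]
    r0: float
    d: float
    e: float
    cost: float
    accepted: bool
    n_evaluations: int = 0
    status: int = 0


@dataclass
class EnsembleResult:
    """Accepted trial subnetworks for one (target gene, experiment)."""

    target: int
    experiment_id: str
    trials: int
    accepted: list[FitResult] = field(default_factory=list)
    seed: int | None = None
    error: str | None = None

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


@dataclass(frozen=True)
class InferenceConfig:
    budget: int = 2000
    batch_size: int = 1600
    acceptance_threshold: float = 0.05
    max_activators: int = 3
    max_inhibitors: int = 3
    param_bounds: tuple[float, float] = (1e-2, 1e2)
    substeps: int = 25
    max_nfev: int = 60
    ftol: float = 1e-4
    xtol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.budget < 0 or self.batch_size < 1:
            raise ModelError("budget must be >= 0 and batch size >= 1")
        lo, hi = self.param_bounds
        if not 0 < lo < hi:
            raise ModelError("parameter bounds must be positive and ordered")
        if self.max_activators + self.max_inhibitors < 1:
            raise ModelError("candidate size distribution must allow >= 1 regulator")


def build_regulator_signals(dataset: TimeCourseDataset, tau: float = 1.0
                            ) -> dict[int, RegulatorSignal]:
    """Cubic-spline interpolant per gene, boundary-clamped outside the data."""
    if dataset.n_timepoints < 4:
        raise ModelError("cubic spline interpolation needs at least 4 timepoints")
    return {g: RegulatorSignal(dataset.timepoints, dataset.matrix[g])
            for g in range(dataset.n_genes)}


class SignalGrid:
    """Delayed regulator values pre-tabulated on a refined time grid.

    Row g holds x_g(t - tau) at every node of the grid obtained by splitting
    each observation interval into ``substeps`` equal steps (delayed lookups
    before the first sample are clamped to it, i.e. constant history).
    Pre-tabulating once per (dataset, tau) makes each trial-fit residual a set
    of cheap array operations.
    """

    def __init__(self, dataset: TimeCourseDataset, tau: float, substeps: int = 100):
        self.dataset = dataset
        self.tau = float(tau)
        self.substeps = int(substeps)
        self.grid, self.obs_idx = refine_timegrid(dataset.timepoints, substeps)
        signals = build_regulator_signals(dataset, tau)
        td = self.grid - tau
        self.delayed = np.vstack([signals[g](td) for g in range(dataset.n_genes)])


def sample_candidate(n_genes: int, target: int, config: InferenceConfig,
                     rng: np.random.Generator) -> CandidateSubnetwork:
    """Random candidate: role-set sizes uniform on the allowed grid minus (0, 0);
    regulators uniform without replacement among the other genes."""
    if n_genes < 2:
        raise ModelError("need at least 2 genes to propose a regulator")
    while True:
        a = int(rng.integers(0, config.max_activators + 1))
        b = int(rng.integers(0, config.max_inhibitors + 1))
        if a + b:
            break
    total = min(a + b, n_genes - 1)
    a = min(a, total)
    b = total - a
    pool = np.delete(np.arange(n_genes), target)
    chosen = rng.choice(pool, size=total, replace=False)
    return CandidateSubnetwork(target=target,
                               activators=tuple(int(g) for g in chosen[:a]),
                               inhibitors=tuple(int(g) for g in chosen[a:]))


def role_inclusion_probability(n_genes: int, config: InferenceConfig) -> float:
    """P(a given gene enters a random candidate in a given role).

    Computed exactly from the candidate-size distribution (uniform over the
    (max_a+1) x (max_b+1) grid minus the empty cell): E[role size] / (N - 1).
    Used as the inclusion probability of the binomial null for edge counts.
    """
    cells = [(a, b) for a in range(config.max_activators + 1)
             for b in range(config.max_inhibitors + 1) if a + b > 0]
    mean_act = sum(a for a, _ in cells) / len(cells)
    return mean_act / (n_genes - 1)


def _pack_bounds(candidate: CandidateSubnetwork, config: InferenceConfig):
    n_par = candidate.size + 3  # per-edge K, then r0, d, e
    lo, hi = np.log(config.param_bounds[0]), np.log(config.param_bounds[1])
    return n_par, lo, hi


def fit_subnetwork(candidate: CandidateSubnetwork, target_series: np.ndarray,
                   grid: SignalGrid, config: InferenceConfig,
                   rng: np.random.Generator | None = None,
                   theta0: np.ndarray | None = None,
                   hill_n: float = 2.0) -> FitResult:
    """Bounded least-squares fit of one candidate to the target time course.

    Free parameters, all searched in log-space within ``config.param_bounds``:
    one binding constant per candidate edge, plus r0, d and e.  The Hill
    coefficient and the delay are fixed.  Cost is the root-mean-square
    residual normalized by the mean of the target series; a candidate is
    accepted when the fit converges below ``config.acceptance_threshold``.

    The starting iterate is log-uniform random within bounds (one start per
    trial; the trial budget buys restarts implicitly) unless ``theta0`` is
    given in log-space.
    """
    y = np.asarray(target_series, dtype=float)
    t = grid.dataset.timepoints
    if y.size != t.size:
        raise ModelError("target series length must match the timepoints")
    scale = float(np.mean(y))
    if scale <= 0:
        return FitResult(candidate, (), (), np.nan, np.nan, np.nan,
                         cost=np.inf, accepted=False, status=-2)
    x0 = float(y[0])
    n_act = len(candidate.activators)
    sig_act = grid.delayed[list(candidate.activators)]
    sig_inh = grid.delayed[list(candidate.inhibitors)]
    norm = scale * np.sqrt(y.size)

    n_par, lo, hi = _pack_bounds(candidate, config)
    if theta0 is None:
        if rng is None:
            raise ModelError("fit_subnetwork needs an rng or an explicit start")
        theta0 = rng.uniform(lo, hi, size=n_par)
    else:
        theta0 = np.clip(np.asarray(theta0, dtype=float), lo, hi)

    def residual(theta: np.ndarray) -> np.ndarray:
        p = np.exp(theta)
        k_act, k_inh = p[:n_act], p[n_act:candidate.size]
        r0, d, e = p[candidate.size:]
        a = (sig_act / k_act[:, None]).sum(axis=0) if n_act else 0.0
        i_ = (sig_inh / k_inh[:, None]).sum(axis=0) if k_inh.size else 0.0
        an = np.asarray(a) ** hill_n
        rate = r0 * (an + e) / (1.0 + np.asarray(i_) ** hill_n + an + e)
        rate = np.broadcast_to(np.asarray(rate, dtype=float), grid.grid.shape)
        x = integrate_linear_production(rate, d, x0, grid.substeps, t)
        return (x - y) / norm

    try:
        with np.errstate(over="raise", invalid="raise"):
            res = least_squares(residual, theta0, bounds=(lo, hi), method="trf",
                                max_nfev=config.max_nfev, ftol=config.ftol,
                                xtol=config.xtol)
    except (FloatingPointError, IntegrationError, ValueError):
        return FitResult(candidate, (), (), np.nan, np.nan, np.nan,
                         cost=np.inf, accepted=False, status=-1)

    p = np.exp(res.x)
    cost = float(np.linalg.norm(res.fun))
    # status < 0 is an optimizer failure; status 0 (eval budget exhausted) still
    # counts when the achieved cost is already below the acceptance threshold.
    accepted = bool(res.status >= 0 and np.isfinite(cost)
                    and cost < config.acceptance_threshold)
    return FitResult(candidate,
                     k_act=tuple(p[:n_act]), k_inh=tuple(p[n_act:candidate.size]),
                     r0=float(p[-3]), d=float(p[-2]), e=float(p[-1]),
                     cost=cost, accepted=accepted,
                     n_evaluations=int(res.nfev), status=int(res.status))


def _trial_rng(master_seed: int, gene: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), gene, trial]))


def run_gene(dataset: TimeCourseDataset, target: int, config: InferenceConfig,
             grid: SignalGrid | None = None, hill_n: float = 2.0,
             tau: float = 1.0) -> EnsembleResult:
    """Sample and fit ``config.budget`` trial subnetworks for one target gene.

    Trials are processed in batches of ``config.batch_size``; per-trial seeds
    depend only on (master seed, gene, trial index), so batching never changes
    the result.  An empty accepted list is a valid outcome.
    """
    if grid is None:
        grid = SignalGrid(dataset, tau=tau, substeps=config.substeps)
    y = dataset.series(target)
    result = EnsembleResult(target=target, experiment_id=dataset.experiment_id,
                            trials=config.budget, seed=config.seed)
    for start in range(0, config.budget, config.batch_size):
        for trial in range(start, min(start + config.batch_size, config.budget)):
            rng = _trial_rng(config.seed, target, trial)
            cand = sample_candidate(dataset.n_genes, target, config, rng)
            fit = fit_subnetwork(cand, y, grid, config, rng=rng, hill_n=hill_n)
            if fit.accepted:
                result.accepted.append(fit)
    return result


def run_all(dataset: TimeCourseDataset, config: InferenceConfig,
            targets: Sequence[int] | None = None, n_workers: int = 1,
            hill_n: float = 2.0, tau: float = 1.0) -> dict[int, EnsembleResult]:
    """Ensemble search for every target gene (embarrassingly parallel).

    Per-gene results are independent and identical for any worker count.
    A failure in one gene is recorded on its EnsembleResult and does not
    abort the sweep.
    """
    targets = list(range(dataset.n_genes)) if targets is None else list(targets)
    grid = SignalGrid(dataset, tau=tau, substeps=config.substeps)

    def one(g: int) -> EnsembleResult:
        try:
            return run_gene(dataset, g, config, grid=grid, hill_n=hill_n, tau=tau)
        except Exception as exc:  # noqa: BLE001 - isolation contract
            return EnsembleResult(target=g, experiment_id=dataset.experiment_id,
                                  trials=0, seed=config.seed, error=str(exc))

    if n_workers == 1:
        results = [one(g) for g in targets]
    else:
        results = Parallel(n_jobs=n_workers)(delayed(one)(g) for g in targets)
    return {r.target: r for r in results}
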