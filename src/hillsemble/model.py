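"""Delayed Hill-kinetics transcription model.

The mRNA level ``x_j`` of gene *j* obeys a mass-balance equation

    dx_j/dt = r_j(t) - d_j * x_j(t),      x_j(0) = x0_j,

where transcription is driven by competitive binding of activating and
inhibiting transcription factors with cooperativity ``n`` and saturation:

    r_j(t) = r0_j * (A^n + e_j) / (1 + I^n + A^n + e_j),
    A = sum_{i in activators} x_i(t - tau) / K_A(i,j),
    I = sum_{i in inhibitors} x_i(t - tau) / K_I(i,j).

``tau`` is a fixed delay standing in for transcription, translation and
post-translational signalling time; ``e_j`` captures external stimulation or
constitutive transcription.  Regulator trajectories enter through cubic-spline
interpolants of sampled time courses, so the single-target problem is a plain
(non-delayed) scalar ODE driven by known signals, while the full network is a
delay differential system solved by the method of steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import lfilter


class ModelError(ValueError):
    """Invalid model structure or parameters."""


class IntegrationError(RuntimeError):
    """Single-target integration failed; carries the offending target index."""

    def __init__(self, message: str, target: int | None = None):
        super().__init__(message)
        self.target = target


class SimulationError(RuntimeError):
    """Full-network simulation produced a non-finite state."""

    def __init__(self, message: str, genes: Sequence[int] = ()):
        super().__init__(message)
        self.genes = tuple(genes)


@dataclass(frozen=True)
class KineticParameters:
    """Per-gene kinetic constants.

    r0   maximal transcription rate (expression / hour)
    d    first-order degradation rate (1 / hour)
    e    external / constitutive transcription term (dimensionless)
    n    Hill cooperativity exponent (> 1)
    tau  transcription/translation delay (hours)
    """

    r0: float
    d: float
    e: float = 0.0
    n: float = 2.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.r0, self.d, self.e, self.n, self.tau)
        if not all(np.isfinite(v) for v in vals):
            raise ModelError(f"non-finite kinetic parameter in {vals}")
        if self.r0 <= 0:
            raise ModelError(f"r0 must be positive, got {self.r0}")
        if self.d < 0 or self.e < 0 or self.tau < 0:
            raise ModelError("d, e and tau must be non-negative")
        if self.n <= 1:
            raise ModelError(f"Hill coefficient must exceed 1, got {self.n}")


@dataclass(frozen=True)
class RegulatorSet:
    """Activator and inhibitor edges into one target: (gene index, K > 0).

    A gene may regulate a given target in only one role; within a role each
    gene appears at most once.
    """

    activators: tuple[tuple[int, float], ...] = ()
    inhibitors: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "activators", tuple((int(i), float(k)) for i, k in self.activators))
        object.__setattr__(self, "inhibitors", tuple((int(i), float(k)) for i, k in self.inhibitors))
        act = [i for i, _ in self.activators]
        inh = [i for i, _ in self.inhibitors]
        if len(set(act)) != len(act) or len(set(inh)) != len(inh):
            raise ModelError("duplicate regulator index within a role")
        if set(act) & set(inh):
            raise ModelError("a regulator cannot be both activator and inhibitor of one target")
        for _, k in self.activators + self.inhibitors:
            if not (np.isfinite(k) and k > 0):
                raise ModelError(f"binding constant must be positive and finite, got {k}")

    @property
    def activator_indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.activators)

    @property
    def inhibitor_indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.inhibitors)

    @property
    def indices(self) -> tuple[int, ...]:
        return self.activator_indices + self.inhibitor_indices

    @property
    def size(self) -> int:
        return len(self.activators) + len(self.inhibitors)


@dataclass(frozen=True)
class SubnetworkModel:
    """One target gene plus its candidate regulators and kinetics."""

    target: int
    regulators: RegulatorSet
    params: KineticParameters
    x0: float = 1.0

    def __post_init__(self) -> None:
        if self.target in self.regulators.indices:
            raise ModelError(f"target {self.target} cannot regulate itself")
        if not (np.isfinite(self.x0) and self.x0 >= 0):
            raise ModelError(f"initial expression must be >= 0, got {self.x0}")


class RegulatorSignal:
    """Cubic-spline interpolant of one gene's time course.

    Reproduces the samples exactly at sample times; outside
    ``[t_min, t_max]`` evaluation is clamped to the boundary value, which
    doubles as the constant pre-experiment history used for delayed lookups.
    """

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        t = np.asarray(times, dtype=float)
        y = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.size < 4:
            raise ModelError("cubic spline interpolation needs at least 4 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ModelError("timepoints must be strictly increasing")
        self.t_min = float(t[0])
        self.t_max = float(t[-1])
        self._spline = CubicSpline(t, y, bc_type="natural")
        self._lo = float(y[0])
        self._hi = float(y[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self._spline(np.clip(t, self.t_min, self.t_max))


@dataclass
class TimeCourseDataset:
    """Expression matrix (genes x timepoints) from one experiment."""

    timepoints: np.ndarray
    matrix: np.ndarray
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.timepoints.ndim != 1 or np.any(np.diff(self.timepoints) <= 0):
            raise ModelError("timepoints must be a strictly increasing 1-d array")
        if self.matrix.shape[1] != self.timepoints.size:
            raise ModelError(
                f"matrix has {self.matrix.shape[1]} columns for {self.timepoints.size} timepoints"
            )
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ModelError("expression values must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.timepoints.size

    def series(self, gene: int) -> np.ndarray:
        return self.matrix[gene]


def production_rate(params: KineticParameters, activator_sum, inhibitor_sum):
    """Hill-kinetics transcription rate for scaled regulator sums.

    ``activator_sum`` / ``inhibitor_sum`` are the already-scaled quantities
    ``sum_i x_i(t - tau) / K_i`` over the respective role sets.  The rate is
    bounded in ``[0, r0]``, non-decreasing in the activator sum and
    non-increasing in the inhibitor sum.
    """
    a = np.asarray(activator_sum, dtype=float)
    i = np.asarray(inhibitor_sum, dtype=float)
    if np.any(a < 0) or np.any(i < 0) or not (np.all(np.isfinite(a)) and np.all(np.isfinite(i))):
        raise ModelError("regulator sums must be finite and non-negative")
    an = a ** params.n
    rate = params.r0 * (an + params.e) / (1.0 + i ** params.n + an + params.e)
    return rate if rate.ndim else float(rate)


def regulator_sums(regulators: RegulatorSet, t, tau: float,
                   signals: Mapping[int, Callable]) -> tuple[float, float]:
    """Scaled activator and inhibitor sums A(t - tau), I(t - tau)."""
    missing = [i for i in regulators.indices if i not in signals]
    if missing:
        raise ModelError(f"no regulator signal supplied for gene(s) {missing}")
    td = t - tau
    a = sum(signals[i](td) / k for i, k in regulators.activators)
    i_ = sum(signals[i](td) / k for i, k in regulators.inhibitors)
    return float(a), float(i_)


def target_rhs(model: SubnetworkModel, t: float, x: float,
               signals: Mapping[int, Callable]) -> float:
    """Right-hand side dx/dt = r(t) - d*x for a single target gene."""
    a, i = regulator_sums(model.regulators, t, model.params.tau, signals)
    return production_rate(model.params, a, i) - model.params.d * float(np.asarray(x).ravel()[0])


def refine_timegrid(timepoints: np.ndarray, substeps: int) -> tuple[np.ndarray, np.ndarray]:
    """Subdivide each observation interval into `substeps` equal steps.

    Returns the fine grid and the indices of the original timepoints in it.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    pieces = [np.array([timepoints[0]])]
    for a, b in zip(timepoints[:-1], timepoints[1:]):
        pieces.append(np.linspace(a, b, substeps + 1)[1:])
    grid = np.concatenate(pieces)
    obs_idx = np.arange(timepoints.size) * substeps
    return grid, obs_idx


def integrate_linear_production(rate_grid: np.ndarray, d: float, x0: float,
                                substeps: int, timepoints: np.ndarray) -> np.ndarray:
    """Integrate dx/dt = r(t) - d*x exactly per step for piecewise-linear r.

    `rate_grid` holds r at the nodes of the refined grid produced by
    :func:`refine_timegrid`.  Within each observation interval the step size
    is constant, so the one-step update x+ = alpha*x + c has constant alpha
    and reduces to a linear recurrence evaluated with a C-level filter.
    Returns x at the original timepoints.
    """
    out = np.empty(timepoints.size)
    out[0] = x = float(x0)
    pos = 0
    for j in range(timepoints.size - 1):
        h = (timepoints[j + 1] - timepoints[j]) / substeps
        r = rate_grid[pos:pos + substeps + 1]
        dr = np.diff(r)
        if d * h > 1e-10:
            alpha = float(np.exp(-d * h))
            phi1 = (1.0 - alpha) / d
            # w2*h = integral weight on the linear ramp of r over one step
            w2 = ((1.0 - alpha) * (h * d - 1.0) + alpha * d * h) / (d * d * h)
        else:
            alpha, phi1, w2 = 1.0 - d * h, h * (1.0 - d * h / 2.0), h / 2.0
        c = r[:-1] * phi1 + dr * w2
        path, _ = lfilter([1.0], [1.0, -alpha], c, zi=np.array([alpha * x]))
        x = float(path[-1])
        out[j + 1] = x
        pos += substeps
    return out


def integrate_target(model: SubnetworkModel, signals: Mapping[int, Callable],
                     timepoints: Sequence[float], *, method: str = "LSODA",
                     rtol: float = 1e-6, atol: float = 1e-9,
                     substeps: int = 100) -> np.ndarray:
    """Trajectory of one target gene at the given timepoints.

    ``method="LSODA"`` (or any ``solve_ivp`` method) uses the adaptive
    stiff/non-stiff solver; ``method="grid"`` uses the fixed-grid exact
    linear-step integrator (the fast path used during ensemble fitting).
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(timepoints) <= 0):
        raise ModelError("timepoints must be strictly increasing")
    p = model.params
    if method == "grid":
        grid, obs_idx = refine_timegrid(timepoints, substeps)
        a = np.zeros(grid.size)
        i_ = np.zeros(grid.size)
        td = grid - p.tau
        for idx, k in model.regulators.activators:
            a += signals[idx](td) / k
        for idx, k in model.regulators.inhibitors:
            i_ += signals[idx](td) / k
        an = a ** p.n
        rate = p.r0 * (an + p.e) / (1.0 + i_ ** p.n + an + p.e)
        return integrate_linear_production(rate, p.d, model.x0, substeps, timepoints)

    sol = solve_ivp(
        lambda t, x: target_rhs(model, t, x, signals),
        (timepoints[0], timepoints[-1]),
        [model.x0],
        t_eval=timepoints,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed for target {model.target}: {sol.message}", target=model.target
        )
    traj = sol.y[0]
    if not np.all(np.isfinite(traj)):
        raise IntegrationError(f"non-finite trajectory for target {model.target}",
                               target=model.target)
    return traj


def simulate_network_dde(topology, params: Sequence[KineticParameters], stimuli,
                         timepoints: Sequence[float], *, x0=None,
                         rtol: float = 1e-6, atol: float = 1e-9) -> TimeCourseDataset:
    """Simulate the full coupled delay-differential network.

    Integration proceeds by the method of steps: each tau-length segment is an
    ODE whose delayed state is read from the dense solution of previous
    segments; the history is constant, x(t) = x0 for t <= t_start.  All genes
    share one delay tau and Hill exponent n.  Per-gene ``e`` terms come from
    ``stimuli`` (zero for unstimulated genes).

    ``topology`` is a :class:`hillsemble.netgen.NetworkTopology`;
    ``stimuli`` a :class:`hillsemble.netgen.StimulusAssignment` or None.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    n = topology.n_genes
    if len(params) != n:
        raise ModelError("need one KineticParameters per gene")
    taus = {p.tau for p in params}
    if len(taus) != 1:
        raise ModelError("all genes must share the delay tau")
    tau = taus.pop()
    hill = {p.n for p in params}
    if len(hill) != 1:
        raise ModelError("all genes must share the Hill coefficient")
    nexp = hill.pop()

    r0 = np.array([p.r0 for p in params])
    d = np.array([p.d for p in params])
    e = np.array([p.e for p in params])
    if stimuli is not None:
        for g, ev in stimuli.e_values.items():
            e[g] = ev
    x0 = np.full(n, 1.0) if x0 is None else np.asarray(x0, dtype=float).copy()

    act_src, act_tgt, act_k, inh_src, inh_tgt, inh_k = topology.edge_arrays()

    t_start, t_end = float(timepoints[0]), float(timepoints[-1])
    segments: list = []  # (t_lo, t_hi, OdeSolution)

    def history(t: float) -> np.ndarray:
        if t <= t_start:
            return x0
        for lo, hi, sol in segments:
            if t <= hi + 1e-12:
                return sol(t)
        raise IntegrationError(f"delayed lookup at t={t} beyond computed segments")

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xd = x if tau == 0 else history(t - tau)
        a = np.bincount(act_tgt, weights=xd[act_src] / act_k, minlength=n) \
            if act_src.size else np.zeros(n)
        i_ = np.bincount(inh_tgt, weights=xd[inh_src] / inh_k, minlength=n) \
            if inh_src.size else np.zeros(n)
        an = a ** nexp
        rate = r0 * (an + e) / (1.0 + i_ ** nexp + an + e)
        return rate - d * x

    if tau == 0:
        seg_bounds = [(t_start, t_end)]
    else:
        edges_t = list(np.arange(t_start, t_end, tau)) + [t_end]
        seg_bounds = [(a, b) for a, b in zip(edges_t[:-1], edges_t[1:]) if b > a]

    state = x0
    for lo, hi in seg_bounds:
        sol = solve_ivp(rhs, (lo, hi), state, method="LSODA", dense_output=True,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"segment [{lo}, {hi}] failed: {sol.message}")
        state = sol.y[:, -1]
        if not np.all(np.isfinite(state)):
            bad = np.where(~np.isfinite(state))[0]
            raise SimulationError(f"non-finite state for genes {bad.tolist()}", genes=bad)
        segments.append((lo, hi, sol.sol))

    cols = []
    for t in timepoints:
        cols.append(x0 if t <= t_start else history(t))
    matrix = np.clip(np.column_stack(cols), 0.0, None)
    return TimeCourseDataset(timepoints=timepoints, matrix=matrix)
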