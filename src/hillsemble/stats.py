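"""Edge scoring, significance selection, experiment combination, evaluation.

The accepted ensemble for a target gene is summarized per (regulator, role)
edge by its appearance count and relative frequency.  Edges are selected
either by a fixed frequency cutoff (0.45 by convention) or by an exact
binomial null: under random candidate sampling each accepted subnetwork
includes a given edge with probability p0, so a count c among M accepted
subnetworks is significant at level alpha when P(X >= c) < alpha for
X ~ Binomial(M, p0).

Predictions from independent experiments are combined by union, intersection,
or a CV-gated intersection: an experiment is informative for a target only if
the target's time course has coefficient of variation above 0.05, and the
intersection is restricted to informative experiments (a single informative
experiment stands alone; with no informative experiment the gate makes no
call and the plain intersection is kept).  The gated result therefore always
contains the plain intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .inference import EnsembleResult
from .netgen import NetworkTopology

CV_INFORMATIVE = 0.05

Edge3 = tuple[int, int, str]  # (target, regulator, role)


@dataclass(frozen=True)
class EdgeScore:
    target: int
    regulator: int
    role: str
    count: int
    frequency: float
    p_value: float = float("nan")


@dataclass
class PredictionSet:
    """Predicted (target, regulator, role) edges with provenance."""

    n_genes: int
    edges: frozenset[Edge3]
    experiments: tuple[str, ...] = ()
    mode: str = "single"
    cutoff: float | None = None

    def __post_init__(self):
        self.edges = frozenset(self.edges)
        for t, r, _ in self.edges:
            if t == r:
                raise ValueError(f"self-edge prediction on gene {t}")

    def edges_for(self, target: int) -> frozenset[tuple[int, str]]:
        return frozenset((r, role) for t, r, role in self.edges if t == target)


def edge_frequencies(ensemble: EnsembleResult, p0: float | None = None) -> list[EdgeScore]:
    """Per-edge appearance counts/frequencies over the accepted ensemble.

    Frequencies are relative to the number of *accepted* subnetworks.  With
    ``p0`` given, attaches the exact binomial-null tail probability
    P(X >= count) for X ~ Binomial(n_accepted, p0).  An empty ensemble yields
    an empty list.
    """
    m = ensemble.n_accepted
    if m == 0:
        return []
    counts: dict[tuple[int, str], int] = {}
    for fit in ensemble.accepted:
        for g in fit.candidate.activators:
            counts[(g, "activator")] = counts.get((g, "activator"), 0) + 1
        for g in fit.candidate.inhibitors:
            counts[(g, "inhibitor")] = counts.get((g, "inhibitor"), 0) + 1
    scores = []
    for (g, role), c in sorted(counts.items()):
        pv = float(binom.sf(c - 1, m, p0)) if p0 is not None else float("nan")
        scores.append(EdgeScore(ensemble.target, g, role, c, c / m, pv))
    return scores


def binomial_null_threshold(n_accepted: int, p0: float, alpha: float) -> int:
    """Smallest count c with P(X >= c) < alpha under X ~ Binomial(M, p0).

    The survival function is evaluated exactly.  alpha >= 1 accepts any count
    (threshold 0); p0 = 0 makes a single appearance significant.
    """
    if n_accepted < 1:
        raise ValueError("ensemble size must be >= 1")
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be a probability")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha >= 1:
        return 0
    for c in range(0, n_accepted + 2):
        if binom.sf(c - 1, n_accepted, p0) < alpha:
            return c
    return n_accepted + 1


def significant_edges(scores: Sequence[EdgeScore], mode: str, value: float,
                      n_accepted: int | None = None, p0: float | None = None,
                      n_genes: int = 0, experiment_id: str = "") -> PredictionSet:
    """Select edges from one target's score list.

    mode="fixed_cutoff": keep frequency >= value (inclusive boundary).
    mode="binomial":     keep count >= binomial_null_threshold(M, p0, value).
    """
    kept: set[Edge3] = set()
    if scores:
        if mode == "fixed_cutoff":
            kept = {(s.target, s.regulator, s.role) for s in scores if s.frequency >= value}
        elif mode == "binomial":
            m = n_accepted if n_accepted is not None else max(s.count for s in scores)
            if p0 is None:
                raise ValueError("binomial mode needs the null inclusion probability p0")
            c_min = binomial_null_threshold(m, p0, value)
            kept = {(s.target, s.regulator, s.role) for s in scores if s.count >= c_min}
        else:
            raise ValueError(f"unknown selection mode {mode!r}")
    return PredictionSet(n_genes=n_genes, edges=frozenset(kept),
                         experiments=(experiment_id,) if experiment_id else (),
                         mode="single", cutoff=value)


def cv_metric(series: Sequence[float]) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean.

    A non-positive mean is flagged uninformative by returning 0.
    """
    y = np.asarray(series, dtype=float)
    if y.size == 0:
        raise ValueError("empty series")
    mean = float(y.mean())
    if mean <= 0 or y.size < 2 or np.ptp(y) == 0:
        return 0.0
    return float(y.std(ddof=1) / mean)


def is_informative(series: Sequence[float], threshold: float = CV_INFORMATIVE) -> bool:
    return cv_metric(series) > threshold


def combine_experiments(predictions: Sequence[PredictionSet], mode: str,
                        informative: Sequence[Mapping[int, bool]] | None = None
                        ) -> PredictionSet:
    """Combine per-experiment predictions into one set.

    union/intersection act per (target, regulator, role).
    cv_gated_intersection intersects only over experiments informative for
    each target; exactly one informative experiment contributes its set
    alone, and with none the plain intersection is kept, so the gated set
    always contains the plain intersection.
    """
    if not predictions:
        raise ValueError("need at least one prediction set")
    universes = {p.n_genes for p in predictions}
    if len(universes) != 1:
        raise ValueError(f"mismatched gene universes: {sorted(universes)}")
    n = universes.pop()
    exps = tuple(e for p in predictions for e in p.experiments)

    if mode == "union":
        edges = frozenset().union(*(p.edges for p in predictions))
    elif mode == "intersection":
        edges = frozenset.intersection(*(p.edges for p in predictions))
    elif mode == "cv_gated_intersection":
        if informative is None or len(informative) != len(predictions):
            raise ValueError("cv_gated_intersection needs one informativeness map per experiment")
        edges_set: set[Edge3] = set()
        targets = {t for p in predictions for (t, _, _) in p.edges} | {
            t for m in informative for t in m
        }
        for t in targets:
            sets = [p.edges_for(t) for p, m in zip(predictions, informative)
                    if m.get(t, True)]
            if not sets:  # no informative experiment: keep the conservative combination
                sets = [p.edges_for(t) for p in predictions]
            common = frozenset.intersection(*sets)
            edges_set |= {(t, r, role) for r, role in common}
        edges = frozenset(edges_set)
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return PredictionSet(n_genes=n, edges=edges, experiments=exps, mode=mode)


def performance_metrics(prediction: PredictionSet, truth: NetworkTopology,
                        role_aware: bool = True,
                        informative: Sequence[Mapping[int, bool]] | None = None
                        ) -> dict[str, float]:
    """True-edge recovery (%) and false positives per gene.

    Matching is role-aware by default (an activator prediction only matches an
    activator edge); set role_aware=False to match on (target, regulator)
    alone.  With per-experiment informativeness maps, also reports the
    fraction of targets informative in both / exactly one / neither
    experiment.
    """
    if role_aware:
        true_edges = {(e.target, e.source, e.role) for e in truth.edges}
        pred = set(prediction.edges)
    else:
        true_edges = {(e.target, e.source) for e in truth.edges}
        pred = {(t, r) for t, r, _ in prediction.edges}
    n_true = len(true_edges)
    tp = len(pred & true_edges)
    fp = len(pred - true_edges)
    out = {
        "recovery_pct": 100.0 * tp / n_true if n_true else 0.0,
        "false_positives_per_gene": fp / truth.n_genes,
        "n_predicted": float(len(pred)),
        "n_true_edges": float(n_true),
    }
    if informative is not None and len(informative) == 2:
        counts = [0, 0, 0]
        for t in range(truth.n_genes):
            k = sum(1 for m in informative if m.get(t, False))
            counts[k] += 1
        out["frac_informative_neither"] = counts[0] / truth.n_genes
        out["frac_informative_one"] = counts[1] / truth.n_genes
        out["frac_informative_both"] = counts[2] / truth.n_genes
    return out
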