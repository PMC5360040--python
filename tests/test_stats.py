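"""Edge scoring, binomial null, CV gate, combination and evaluation tests."""

import math

import numpy as np
import pytest

from hillsemble.inference import CandidateSubnetwork, EnsembleResult, FitResult
from hillsemble.netgen import Edge, NetworkTopology
from hillsemble.stats import (
    PredictionSet,
    binomial_null_threshold,
    combine_experiments,
    cv_metric,
    edge_frequencies,
    is_informative,
    performance_metrics,
    significant_edges,
)


def make_ensemble(target, members):
    """members: list of (activators, inhibitors) tuples."""
    res = EnsembleResult(target=target, experiment_id="e1", trials=len(members))
    for act, inh in members:
        cand = CandidateSubnetwork(target, tuple(act), tuple(inh))
        res.accepted.append(FitResult(cand, (), (), 1, 1, 0, cost=0.01, accepted=True))
    return res


def exact_binom_tail(c, m, p):
    """P(X >= c) by exact enumeration with math.comb (independent of scipy)."""
    return sum(math.comb(m, k) * p ** k * (1 - p) ** (m - k) for k in range(c, m + 1))


class TestEdgeFrequencies:
    def test_unanimous_edge(self):
        ens = make_ensemble(0, [((8,), ()), ((8, 2), ()), ((8,), (3,)), ((8,), ())])
        scores = {(s.regulator, s.role): s.frequency for s in edge_frequencies(ens)}
        assert scores[(8, "activator")] == 1.0
        assert scores[(2, "activator")] == 0.25

    def test_partial_frequency(self):
        ens = make_ensemble(0, [((1,), ()), ((1,), ()), ((2,), ()), ((2,), ()), ((3,), ())])
        scores = {(s.regulator, s.role): s.frequency for s in edge_frequencies(ens)}
        assert scores[(1, "activator")] == pytest.approx(0.4)

    def test_empty_ensemble_gives_empty_scores(self):
        assert edge_frequencies(EnsembleResult(0, "e1", trials=10)) == []

    def test_counts_match_brute_force_recount(self, tmp_path):
        from hillsemble.io import read_ensembles, write_ensembles

        rng = np.random.default_rng(0)
        members = [
            (tuple(rng.choice(np.arange(1, 9), size=rng.integers(1, 3), replace=False)),
             ())
            for _ in range(30)
        ]
        ens = make_ensemble(0, members)
        write_ensembles({0: ens}, tmp_path / "e.json", n_genes=9, p0_role=0.2)
        loaded, _ = read_ensembles(tmp_path / "e.json")
        tally: dict = {}
        for fit in loaded[0].accepted:
            for g in fit.candidate.activators:
                tally[g] = tally.get(g, 0) + 1
        for s in edge_frequencies(ens):
            assert s.count == tally[s.regulator]


class TestBinomialNull:
    def test_alpha_one_accepts_everything(self):
        assert binomial_null_threshold(10, 0.3, 1.0) == 0

    def test_impossible_null_needs_single_count(self):
        assert binomial_null_threshold(10, 0.0, 0.01) == 1

    def test_exact_tail_enumeration_case(self):
        # smallest c with P(Bin(10, 0.1) >= c) < 0.01
        assert exact_binom_tail(4, 10, 0.1) >= 0.01
        assert exact_binom_tail(5, 10, 0.1) < 0.01
        assert binomial_null_threshold(10, 0.1, 0.01) == 5

    @pytest.mark.parametrize("m,p0", [(10, 0.05), (10, 0.1), (50, 0.05), (50, 0.1)])
    def test_matches_independent_enumeration(self, m, p0):
        for alpha in (0.01, 0.05):
            c = binomial_null_threshold(m, p0, alpha)
            assert exact_binom_tail(c, m, p0) < alpha
            if c > 0:
                assert exact_binom_tail(c - 1, m, p0) >= alpha

    def test_monotone_in_alpha(self):
        thresholds = [binomial_null_threshold(50, 0.1, a)
                      for a in (0.001, 0.01, 0.05, 0.2, 1.0)]
        assert thresholds == sorted(thresholds, reverse=True)


class TestSignificantEdges:
    def test_inclusive_cutoff_boundary(self):
        ens = make_ensemble(0, [((1,), ()) for _ in range(100)])
        scores = edge_frequencies(ens)
        scores += [
            type(scores[0])(0, 2, "activator", 45, 0.45, float("nan")),
            type(scores[0])(0, 3, "activator", 44, 0.44, float("nan")),
        ]
        pred = significant_edges(scores, "fixed_cutoff", 0.45, n_genes=10)
        kept = {(r, role) for _, r, role in pred.edges}
        assert kept == {(1, "activator"), (2, "activator")}

    def test_empty_scores(self):
        pred = significant_edges([], "fixed_cutoff", 0.45, n_genes=5)
        assert pred.edges == frozenset()

    def test_binomial_mode_matches_hand_tally(self):
        # 5-gene toy: edge seen 5 of 6 accepted, null p0=0.4
        ens = make_ensemble(0, [((1,), ())] * 5 + [((2,), ())])
        scores = edge_frequencies(ens)
        c_min = binomial_null_threshold(6, 0.4, 0.05)
        pred = significant_edges(scores, "binomial", 0.05, n_accepted=6, p0=0.4,
                                 n_genes=5)
        kept = {r for _, r, _ in pred.edges}
        assert kept == {s.regulator for s in scores if s.count >= c_min}
        assert 1 in kept and 2 not in kept


class TestCvMetric:
    def test_constant_series_uninformative(self):
        assert cv_metric([2.0] * 12 ) == 0.0
        assert not is_informative([2.0] * 12)

    def test_sample_sd_convention(self):
        assert cv_metric([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        y = np.random.default_rng(1).uniform(0.5, 2.0, 12)
        assert cv_metric(y) == pytest.approx(cv_metric(7.3 * y))

    def test_nonpositive_mean_flagged_uninformative(self):
        assert cv_metric([0.0, 0.0, 0.0]) == 0.0


def pset(n, triples, exp=("e",)):
    return PredictionSet(n_genes=n, edges=frozenset(triples), experiments=exp)


class TestCombination:
    def test_intersection_and_union(self):
        a = pset(5, {(0, 1, "activator"), (0, 2, "activator"), (1, 3, "inhibitor")})
        b = pset(5, {(0, 2, "activator"), (1, 3, "inhibitor"), (2, 4, "activator")})
        assert combine_experiments([a, b], "union").edges == a.edges | b.edges
        assert combine_experiments([a, b], "intersection").edges == a.edges & b.edges

    def test_cv_gate_single_informative_experiment_stands_alone(self):
        a = pset(5, {(0, 1, "activator")})
        b = pset(5, {(0, 2, "activator")})
        info = [{0: False}, {0: True}]
        out = combine_experiments([a, b], "cv_gated_intersection", informative=info)
        assert out.edges == b.edges

    def test_cv_gate_no_informative_experiment_keeps_intersection(self):
        a = pset(5, {(0, 1, "activator"), (0, 2, "activator")})
        b = pset(5, {(0, 1, "activator"), (0, 3, "activator")})
        info = [{0: False}, {0: False}]
        out = combine_experiments([a, b], "cv_gated_intersection", informative=info)
        assert out.edges == a.edges & b.edges

    def test_cv_gated_always_contains_plain_intersection(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            mk = lambda: pset(6, {(int(t), int(r), "activator")
                                  for t, r in rng.integers(0, 6, (8, 2)) if t != r})
            a, b = mk(), mk()
            info = [{g: bool(rng.random() < 0.5) for g in range(6)} for _ in range(2)]
            cvg = combine_experiments([a, b], "cv_gated_intersection", informative=info)
            inter = combine_experiments([a, b], "intersection")
            assert inter.edges <= cvg.edges

    def test_union_contains_inputs_contain_intersection(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mk = lambda: pset(8, {(int(t), int(r), "activator")
                                  for t, r in rng.integers(0, 8, (10, 2)) if t != r})
            a, b = mk(), mk()
            u = combine_experiments([a, b], "union").edges
            i = combine_experiments([a, b], "intersection").edges
            assert i <= a.edges <= u and i <= b.edges <= u

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            combine_experiments([pset(5, set()), pset(6, set())], "union")


class TestPerformanceMetrics:
    TRUTH = NetworkTopology(5, tuple(
        Edge(s, t, r, 1.0) for s, t, r in [
            (1, 0, "activator"), (2, 0, "inhibitor"), (3, 1, "activator"),
            (4, 2, "activator"), (0, 3, "inhibitor"), (1, 3, "activator"),
            (2, 4, "inhibitor"), (3, 4, "activator"), (0, 2, "activator"),
            (4, 1, "inhibitor"),
        ]))

    def test_perfect_prediction(self):
        pred = pset(5, {(e.target, e.source, e.role) for e in self.TRUTH.edges})
        m = performance_metrics(pred, self.TRUTH)
        assert m["recovery_pct"] == 100.0
        assert m["false_positives_per_gene"] == 0.0

    def test_empty_prediction(self):
        m = performance_metrics(pset(5, set()), self.TRUTH)
        assert m["recovery_pct"] == 0.0
        assert m["false_positives_per_gene"] == 0.0

    def test_hand_counted_mixture(self):
        true_subset = list(self.TRUTH.edges)[:4]
        edges = {(e.target, e.source, e.role) for e in true_subset}
        # six spurious predictions, role-aware misses included
        spurious = {(0, 3, "activator"), (0, 4, "activator"), (1, 2, "activator"),
                    (2, 3, "inhibitor"), (3, 4, "inhibitor"), (4, 0, "activator")}
        m = performance_metrics(pset(5, edges | spurious), self.TRUTH)
        assert m["recovery_pct"] == pytest.approx(40.0)
        assert m["false_positives_per_gene"] == pytest.approx(1.2)

    def test_role_agnostic_matching(self):
        pred = pset(5, {(0, 1, "inhibitor")})  # wrong role for a true edge
        strict = performance_metrics(pred, self.TRUTH)
        loose = performance_metrics(pred, self.TRUTH, role_aware=False)
        assert strict["recovery_pct"] == 0.0
        assert loose["recovery_pct"] == pytest.approx(10.0)

    def test_informativeness_tally(self):
        info = [{g: g < 3 for g in range(5)}, {g: g in (0, 4) for g in range(5)}]
        m = performance_metrics(pset(5, set()), self.TRUTH, informative=info)
        assert m["frac_informative_both"] == pytest.approx(0.2)  # gene 0
        assert m["frac_informative_one"] == pytest.approx(0.6)   # genes 1, 2, 4
        assert m["frac_informative_neither"] == pytest.approx(0.2)  # gene 3
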