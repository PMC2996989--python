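import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episens.interactions import (
    CallRecord,
    InteractionCallSet,
    call_by_threshold,
    call_top_k,
    cobinding_test,
    compare_call_sets,
    delta_f_vs_s,
    enrichment_test,
    predictive_value_curve,
)
from episens.io import EvidenceTable, ValidationError
from episens.simulate import E1, E2, generate_library, scenario_spec
from episens.workflow import analyze_library


def _frame(rows):
    return pd.DataFrame(rows, columns=["gene1", "gene2", "family", "environment", "epsilon", "p_value"])


def _s_rows(entries):
    return _frame(
        [dict(gene1=a, gene2=b, family="S", environment="cross-environment", epsilon=e, p_value=p)
         for a, b, e, p in entries]
    )


class TestCallByThreshold:
    def test_strict_threshold(self):
        scores = _s_rows([("A", "B", -0.4, 0.005), ("A", "C", 0.2, 0.02), ("B", "C", 0.01, 0.5)])
        calls = call_by_threshold(scores, alpha=0.01)
        assert len(calls) == 1
        assert calls.calls[0].genes == ("A", "B")

    def test_alpha_one_calls_everything(self):
        scores = _s_rows([("A", "B", -0.4, 0.005), ("A", "C", 0.2, 0.02), ("B", "C", 0.01, 0.5)])
        assert len(call_by_threshold(scores, alpha=1.0)) == 3

    def test_f_family_pair_called_once_with_assignment(self):
        rows = []
        for env, p in ((E1, 0.004), (E2, 0.003)):
            rows.append(dict(gene1="A", gene2="B", family="F", environment=env, epsilon=0.3, p_value=p))
        calls = call_by_threshold(_frame(rows), alpha=0.01, family="F", env_order=(E1, E2))
        assert len(calls) == 1
        assert calls.calls[0].environment == "both"

    def test_calls_sorted_by_p(self):
        scores = _s_rows([("A", "B", -0.4, 0.04), ("A", "C", 0.2, 0.001), ("B", "C", 0.5, 0.02)])
        calls = call_by_threshold(scores, alpha=0.05)
        assert [c.p_value for c in calls.calls] == sorted(c.p_value for c in calls.calls)


class TestCallTopK:
    def test_k_lowest(self):
        scores = _s_rows([("A", "B", -0.4, 0.04), ("A", "C", 0.2, 0.001), ("B", "C", 0.5, 0.02)])
        calls = call_top_k(scores, k=2)
        assert {c.genes for c in calls.calls} == {("A", "C"), ("B", "C")}

    def test_k_zero_empty(self):
        scores = _s_rows([("A", "B", -0.4, 0.04)])
        assert len(call_top_k(scores, k=0)) == 0

    def test_k_too_large_rejected(self):
        scores = _s_rows([("A", "B", -0.4, 0.04)])
        with pytest.raises(ValidationError):
            call_top_k(scores, k=2)

    def test_boundary_tie_resolved_by_abs_epsilon_then_name(self):
        scores = _s_rows(
            [("A", "B", -0.1, 0.02), ("A", "C", -0.5, 0.02), ("A", "D", 0.5, 0.02), ("B", "C", 0.9, 0.001)]
        )
        calls = call_top_k(scores, k=2)
        # P tie at 0.02: |eps| 0.5 beats 0.1; name tie (A,C) vs (A,D) -> (A,C)
        assert [c.genes for c in calls.calls] == [("B", "C"), ("A", "C")]
        again = call_top_k(scores.sample(frac=1, random_state=0), k=2)
        assert [c.genes for c in again.calls] == [c.genes for c in calls.calls]


class TestCompareCallSets:
    def _set(self, pairs, method="S"):
        return InteractionCallSet(
            method=method,
            calls=[CallRecord(frozenset(p), 0.1, 0.01, "cross-environment") for p in pairs],
            selection_rule="fixture",
        )

    def test_identical(self):
        a = self._set([("A", "B"), ("C", "D")])
        overlap = compare_call_sets(a, a)
        assert overlap.sizes == (2, 0, 0)

    def test_disjoint(self):
        overlap = compare_call_sets(self._set([("A", "B")]), self._set([("C", "D")]))
        assert overlap.sizes == (0, 1, 1)

    def test_swap_symmetry(self):
        a, b = self._set([("A", "B"), ("C", "D")]), self._set([("C", "D"), ("E", "F")])
        ab, ba = compare_call_sets(a, b), compare_call_sets(b, a)
        assert ab.shared == ba.shared
        assert ab.only_a == ba.only_b and ab.only_b == ba.only_a


class TestEnrichment:
    def _calls(self, n, evidence_pairs, n_hits):
        pairs = list(evidence_pairs)[:n_hits] + [frozenset({f"N{i}", f"M{i}"}) for i in range(n - n_hits)]
        return InteractionCallSet(
            method="S",
            calls=[CallRecord(p, -0.3, 0.01, "cross-environment") for p in pairs],
            selection_rule="fixture",
        )

    def test_reported_fold_enrichment_scale(self):
        """9 evidence hits among 37 calls over a 316-pair universe with 26
        evidence pairs is a ~3-fold enrichment at P ~ 0.001."""
        evidence = EvidenceTable(
            {frozenset({f"A{i}", f"B{i}"}): {"buffering"} for i in range(26)}, universe_size=316
        )
        calls = self._calls(37, evidence.pairs_with("buffering"), 9)
        res = enrichment_test(calls, evidence, "buffering")
        assert res.fold_r == pytest.approx((9 / 37) / (26 / 316))
        assert round(res.fold_r, 1) == 3.0
        assert res.p_value < 0.005

    def test_expected_hits_give_unit_fold(self):
        evidence = EvidenceTable(
            {frozenset({f"A{i}", f"B{i}"}): {"buffering"} for i in range(10)}, universe_size=100
        )
        calls = self._calls(20, evidence.pairs_with("buffering"), 2)
        assert enrichment_test(calls, evidence, "buffering").fold_r == pytest.approx(1.0)

    def test_empty_calls_rejected(self):
        evidence = EvidenceTable({frozenset({"A", "B"}): {"buffering"}}, universe_size=10)
        empty = InteractionCallSet(method="S", calls=[], selection_rule="none")
        with pytest.raises(ValidationError):
            enrichment_test(empty, evidence, "buffering")

    def test_hypergeometric_matches_exhaustive_enumeration(self):
        """Brute-force oracle: enumerate every draw of n calls from a small
        universe and count draws with >= k evidence pairs."""
        universe, n_evidence, n_calls = 10, 4, 5
        evidence_ids = set(range(n_evidence))
        for k in range(0, n_evidence + 1):
            total = hits = 0
            for combo in itertools.combinations(range(universe), n_calls):
                total += 1
                if len(evidence_ids & set(combo)) >= k:
                    hits += 1
            expected = hits / total
            p = float(stats.hypergeom.sf(k - 1, universe, n_evidence, n_calls))
            assert p == pytest.approx(expected, abs=1e-12)


class TestCobinding:
    def test_disjoint_targets_not_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        p = cobinding_test({"g1", "g2"}, {"g3", "g4"}, universe)
        assert p > 0.9

    def test_identical_targets_extreme(self):
        universe = {f"g{i}" for i in range(100)}
        targets = {f"g{i}" for i in range(10)}
        assert cobinding_test(targets, targets, universe) < 1e-10

    def test_matches_enumeration_small_universe(self):
        universe = list(range(12))
        a, b = set(range(5)), set(range(3, 9))
        k = len(a & b)
        total = hits = 0
        for combo in itertools.combinations(universe, len(b)):
            total += 1
            if len(a & set(combo)) >= k:
                hits += 1
        p = cobinding_test(a, b, set(universe))
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            cobinding_test({"a"}, {"b"}, set())


class TestDeltaFvsS:
    def test_single_pair_correlation_undefined(self):
        rows = [
            dict(gene1="A", gene2="B", family="F", environment=E1, epsilon=0.1, p_value=0.5),
            dict(gene1="A", gene2="B", family="F", environment=E2, epsilon=0.3, p_value=0.5),
            dict(gene1="A", gene2="B", family="S", environment="cross-environment", epsilon=-0.2, p_value=0.5),
        ]
        res = delta_f_vs_s(_frame(rows))
        assert len(res.table) == 1
        assert res.pearson_r is None

    def test_pairs_missing_scores_counted(self):
        rows = [
            dict(gene1="A", gene2="B", family="F", environment=E1, epsilon=0.1, p_value=0.5),
            dict(gene1="A", gene2="B", family="F", environment=E2, epsilon=0.3, p_value=0.5),
            dict(gene1="A", gene2="B", family="S", environment="cross-environment", epsilon=-0.2, p_value=0.5),
            dict(gene1="A", gene2="C", family="S", environment="cross-environment", epsilon=-0.2, p_value=0.5),
        ]
        res = delta_f_vs_s(_frame(rows))
        assert res.n_excluded == 1

    def test_modulated_library_shows_positive_correlation(self):
        table, _ = generate_library(scenario_spec("complex", 5))
        scores = analyze_library(table, E1, E2, n_trials=1000, seed=5)
        res = delta_f_vs_s(scores, E1, E2)
        assert res.pearson_r is not None and res.pearson_r > 0.5


class TestPredictiveValue:
    def _scores(self):
        return _s_rows(
            [("A", "B", -0.4, 0.004), ("A", "C", 0.3, 0.02), ("B", "C", 0.1, 0.2), ("B", "D", 0.2, 0.04)]
        )

    def test_full_evidence_gives_unit_predictive_value(self):
        evidence = EvidenceTable(
            {frozenset(p): {"buffering"} for p in [("A", "B"), ("A", "C"), ("B", "C"), ("B", "D")]},
            universe_size=4,
        )
        curve = predictive_value_curve(self._scores(), evidence, alphas=[0.01, 0.05, 1.0], families=("S",))
        assert (curve["predictive_value"] == 1.0).all()

    def test_no_evidence_gives_zero(self):
        evidence = EvidenceTable({}, universe_size=4)
        curve = predictive_value_curve(self._scores(), evidence, alphas=[0.05], families=("S",))
        assert (curve["predictive_value"] == 0.0).all()

    def test_rates_monotone_in_alpha(self):
        evidence = EvidenceTable(
            {frozenset({"A", "B"}): {"buffering"}, frozenset({"B", "C"}): {"direct_binding"}},
            universe_size=4,
        )
        curve = predictive_value_curve(self._scores(), evidence, alphas=[0.01, 0.05, 0.5, 1.0], families=("S",))
        assert curve["tpr"].is_monotonic_increasing
        assert curve["fpr"].is_monotonic_increasing
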