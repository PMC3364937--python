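"""Pair classification, reliability/coverage, summaries, rank test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annotrack.annotations import Selector, drop_contradictory_pairs, filter_corpus
from annotrack.propagation import build_closure, closure_difference
from annotrack.quality import (
    CONFIRMED,
    REJECTED_EXPLICIT,
    REMOVED,
    UNINFORMATIVE,
    EvaluationConfig,
    classify_pairs,
    compare_intervals,
    coverage_by_term,
    evaluate_release_pair,
    pooled_reliability,
    reliability_by_term,
    summarize_distribution,
)
from conftest import A, B, C, R, corpus
from oracles import exact_mwu_two_sided, oracle_classify, oracle_coverage, random_instance


def closures(graph, old_rows, new_rows):
    """Build the four stratified closures + the 'new reference' difference."""
    old, _ = drop_contradictory_pairs(corpus(old_rows, "old"))
    new, _ = drop_contradictory_pairs(corpus(new_rows, "new"))
    elec = Selector.of(categories={"electronic"})
    expc = Selector.of(categories={"experimental"})
    old_eval = build_closure(filter_corpus(old, elec), graph)
    new_eval = build_closure(filter_corpus(new, elec), graph)
    old_ref = build_closure(filter_corpus(old, expc), graph)
    new_ref = build_closure(filter_corpus(new, expc), graph)
    return old_eval, new_eval, old_ref, new_ref, closure_difference(new_ref, old_ref)


class TestClassifyPairs:
    def test_exact_confirmation_confirms_all_ancestors(self, chain_graph):
        old_eval, new_eval, _or, _nr, new_new = closures(
            chain_graph,
            [("g", "", B, "IEA")],
            [("g", "", B, "IEA"), ("g", "", B, "IDA", "PMID:1")],
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert cls == {("g", B): CONFIRMED, ("g", A): CONFIRMED, ("g", R): CONFIRMED}

    def test_less_specific_confirmation_leaves_deeper_pairs_uninformative(
        self, chain_graph
    ):
        # new experimental annotation at A only: B stays uninformative because
        # the retained electronic annotation still implies it
        old_eval, new_eval, _or, _nr, new_new = closures(
            chain_graph,
            [("g", "", B, "IEA")],
            [("g", "", B, "IEA"), ("g", "", A, "IDA", "PMID:1")],
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert cls == {
            ("g", A): CONFIRMED, ("g", R): CONFIRMED, ("g", B): UNINFORMATIVE
        }

    def test_disappearance_removes_whole_closure(self, chain_graph):
        old_eval, new_eval, _or, _nr, new_new = closures(
            chain_graph, [("g", "", B, "IEA")], []
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert set(cls.values()) == {REMOVED} and len(cls) == 3

    def test_specialization_is_not_removal(self, chain_graph):
        # electronic A replaced by electronic descendant B: nothing removed
        old_eval, new_eval, _or, _nr, new_new = closures(
            chain_graph, [("g", "", A, "IEA")], [("g", "", B, "IEA")]
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert cls == {("g", A): UNINFORMATIVE, ("g", R): UNINFORMATIVE}

    def test_not_rejects_exact_term_only(self, chain_graph):
        # curator replaces the electronic annotation with a NOT at B:
        # only (g, B) is explicitly rejected — NOT never propagates, so the
        # ancestor pairs are implicit removals, not rejections
        old_eval, new_eval, _or, _nr, new_new = closures(
            chain_graph,
            [("g", "", B, "IEA")],
            [("g", "NOT", B, "IDA", "PMID:1")],
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert cls[("g", B)] == REJECTED_EXPLICIT
        assert cls[("g", A)] == REMOVED and cls[("g", R)] == REMOVED

    def test_explicit_rejection_beats_confirmation(self, four_term_graph):
        # NOT at A arrives together with an experimental descendant B
        old_eval, new_eval, _or, _nr, new_new = closures(
            four_term_graph,
            [("g", "", A, "IEA")],
            [("g", "NOT", A, "IDA", "PMID:1"), ("g", "", B, "IDA", "PMID:2")],
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert cls[("g", A)] == REJECTED_EXPLICIT
        assert cls[("g", R)] == CONFIRMED

    def test_old_experimental_pairs_are_not_new(self, chain_graph):
        # the same experimental annotation existed in the old release:
        # it confirms nothing
        old_eval, new_eval, _or, _nr, new_new = closures(
            chain_graph,
            [("g", "", B, "IEA"), ("g", "", B, "IDA", "PMID:1")],
            [("g", "", B, "IEA"), ("g", "", B, "IDA", "PMID:1")],
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert set(cls.values()) == {UNINFORMATIVE}

    def test_mixed_graphs_rejected(self, chain_graph, diamond_graph):
        a = build_closure(corpus([("g", "", A, "IEA")]), chain_graph)
        b = build_closure(corpus([("g", "", A, "IEA")]), diamond_graph)
        with pytest.raises(ValueError, match="different ontologies"):
            classify_pairs(a, a, b)

    def test_every_pair_gets_exactly_one_label(self, chain_graph):
        old_eval, new_eval, _or, _nr, new_new = closures(
            chain_graph,
            [("g", "", B, "IEA"), ("h", "", A, "IEA")],
            [("g", "", B, "IEA")],
        )
        cls = classify_pairs(old_eval, new_eval, new_new)
        assert set(cls) == set(old_eval.pairs())
        assert all(v in (CONFIRMED, REJECTED_EXPLICIT, REMOVED, UNINFORMATIVE)
                   for v in cls.values())


class TestWorkedFixture:
    def test_reliability_values(self, worked_release_pair):
        graph, old, new = worked_release_pair
        cfg = EvaluationConfig(min_old_annotations=1, min_new_experimental=1)
        df = evaluate_release_pair(old, new, graph, config=cfg).set_index("term")
        assert df.loc[A, "n_confirmed"] == 1
        assert df.loc[A, "n_rejected_explicit"] == 1
        assert df.loc[A, "n_removed"] == 1
        assert df.loc[A, "reliability"] == pytest.approx(1 / 3)
        assert df.loc[B, "reliability"] == pytest.approx(0.5)
        assert df.loc[R, "reliability"] == pytest.approx(1 / 3)

    def test_identical_releases_all_uninformative(self, worked_release_pair):
        graph, old, _new = worked_release_pair
        cfg = EvaluationConfig(min_old_annotations=1, min_new_experimental=1)
        df = evaluate_release_pair(old, old, graph, config=cfg)
        assert (df["n_confirmed"] == 0).all()
        assert (df["n_removed"] == 0).all()
        assert df["reliability"].isna().all()

    def test_default_thresholds_leave_tiny_fixture_unreportable(
        self, worked_release_pair
    ):
        graph, old, new = worked_release_pair
        df = evaluate_release_pair(old, new, graph)  # 10/10 defaults
        assert not df["reportable"].any()


class TestCoverage:
    def test_sibling_missed_ancestors_predicted(self, four_term_graph):
        # old electronic at C; new experimental at sibling B
        old_eval, _ne, old_ref, new_ref, _nn = closures(
            four_term_graph,
            [("g", "", C, "IEA")],
            [("g", "", B, "IDA", "PMID:1")],
        )
        cov = coverage_by_term(old_eval, old_ref, new_ref)
        assert cov[B] == (0, 1, 0.0)
        assert cov[A] == (1, 0, 1.0)
        assert cov[R] == (1, 0, 1.0)

    def test_full_anticipation_gives_coverage_one(self, chain_graph):
        old_eval, _ne, old_ref, new_ref, _nn = closures(
            chain_graph,
            [("g", "", B, "IEA")],
            [("g", "", B, "IDA", "PMID:1")],
        )
        cov = coverage_by_term(old_eval, old_ref, new_ref)
        assert all(v.coverage == 1.0 for v in cov.values())

    def test_no_electronic_annotations_coverage_zero(self, chain_graph):
        old_eval, _ne, old_ref, new_ref, _nn = closures(
            chain_graph, [], [("g", "", B, "IDA", "PMID:1")]
        )
        cov = coverage_by_term(old_eval, old_ref, new_ref)
        assert all(v.coverage == 0.0 for v in cov.values())


class TestReliabilityByTerm:
    def test_undefined_when_all_uninformative(self):
        rel = reliability_by_term({("g", A): UNINFORMATIVE})
        assert rel[A].reliability is None

    def test_monotonicity_in_confirmations(self):
        base = {("g1", A): CONFIRMED, ("g2", A): REMOVED}
        more = dict(base)
        more[("g3", A)] = CONFIRMED
        assert (reliability_by_term(more)[A].reliability
                > reliability_by_term(base)[A].reliability)
        worse = dict(base)
        worse[("g3", A)] = REMOVED
        assert (reliability_by_term(worse)[A].reliability
                < reliability_by_term(base)[A].reliability)

    def test_pooled_reliability_subset(self):
        cls = {("g", A): CONFIRMED, ("g", R): CONFIRMED, ("h", A): REMOVED}
        assert pooled_reliability(cls) == pytest.approx(2 / 3)
        assert pooled_reliability(cls, pairs=[("g", A), ("h", A)]) == 0.5
        assert pooled_reliability({("g", A): UNINFORMATIVE}) is None


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_match_literal_rules(self, seed):
        rng = np.random.default_rng(seed)
        (graph, genes, old_eval_d, old_ref_d, old_not_d,
         new_eval_d, new_ref_d, new_not_d) = random_instance(rng)

        from annotrack.annotations import AnnotationCorpus, AnnotationRecord

        def mk(pos, neg, evidence):
            recs = []
            for g in genes:
                for t in pos.get(g, ()):
                    recs.append(AnnotationRecord(gene=g, term=t, evidence=evidence))
                for t in neg.get(g, ()):
                    recs.append(AnnotationRecord(gene=g, term=t, qualifier="NOT",
                                                 evidence=evidence))
            return AnnotationCorpus(records=recs)

        old_eval = build_closure(mk(old_eval_d, {}, "IEA"), graph)
        new_eval = build_closure(mk(new_eval_d, {}, "IEA"), graph)
        old_ref = build_closure(mk(old_ref_d, old_not_d, "IDA"), graph)
        new_ref = build_closure(mk(new_ref_d, new_not_d, "IDA"), graph)
        cls = classify_pairs(old_eval, new_eval, closure_difference(new_ref, old_ref))
        expected = oracle_classify(graph, old_eval_d, new_eval_d,
                                   old_ref_d, new_ref_d, old_not_d, new_not_d)
        assert cls == expected

        cov = coverage_by_term(old_eval, old_ref, new_ref)
        expected_cov = oracle_coverage(graph, old_eval_d, old_ref_d, new_ref_d)
        assert {t: (v.n_predicted, v.n_missed) for t, v in cov.items()} == expected_cov


class TestSummaries:
    def test_simple_median_mean(self):
        s = summarize_distribution([0, 0, 1, 1])
        assert s.median == 0.5 and s.mean == 0.5

    def test_constant_list_no_outliers(self):
        s = summarize_distribution([0.3] * 7)
        assert s.q1 == s.median == s.q3 == s.mean == 0.3
        assert s.outliers == ()

    def test_outlier_flagged_beyond_iqr_fence(self):
        s = summarize_distribution([0.1] * 9 + [0.9])
        assert s.outliers == (0.9,)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_distribution([])

    def test_quartiles_linear_interpolation(self):
        s = summarize_distribution([1, 2, 3, 4])
        assert s.q1 == pytest.approx(1.75)
        assert s.q3 == pytest.approx(3.25)


class TestCompareIntervals:
    def test_identical_samples_not_significant(self):
        res = compare_intervals([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p >= 0.99 and not res.significant

    def test_complete_separation_u_zero(self):
        res = compare_intervals([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 5), (6, 4), (8, 8)])
    def test_exact_p_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        pooled = rng.permutation(100)[: n + m]  # distinct -> tie-free
        a, b = list(pooled[:n]), list(pooled[n:])
        res = compare_intervals(a, b)
        assert res.p == pytest.approx(exact_mwu_two_sided(a, b), abs=1e-12)
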