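"""Ranking methods and ranking-quality metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simsignal import (
    ValidationError,
    auroc,
    auroc_trapezoid,
    evaluate,
    pauroc,
    pr_curve,
    precision_at_k,
    rank,
)
from simsignal.evaluation import RankedItem, RankedList, roc_points
from simsignal.scoring import LOOScore
from simsignal.datamodel import Measure

from conftest import make_candidates, make_reference


def ranked_from_labels(labels, ade="ade", method="similarity"):
    """RankedList already in order; labels given top-first."""
    items = tuple(
        RankedItem(drug_id=f"d{i}", sort_key=float(len(labels) - i), label=lab)
        for i, lab in enumerate(labels)
    )
    return RankedList(ade_name=ade, method=method, items=items)


def loo(drug_id, score):
    return LOOScore(drug_id, Measure.MACCS2D, "difference", 0.0, "-", 0.0, "-", score)


@pytest.fixture
def labeled_candidates():
    ref = make_reference(
        "ade",
        [("A", "positive", "c"), ("B", "negative", "c"), ("C", "positive", "c")],
    )
    cands = make_candidates("ade", [("A", 1.2, 0.001), ("B", 3.3, 0.04), ("C", 2.0, 0.01)])
    return cands, ref


class TestRank:
    def test_p_value_ascending(self, labeled_candidates):
        cands, ref = labeled_candidates
        ranked = rank(cands, ref, "p_value")
        assert [it.drug_id for it in ranked.items] == ["A", "C", "B"]

    def test_rr_descending(self, labeled_candidates):
        cands, ref = labeled_candidates
        ranked = rank(cands, ref, "rr")
        assert [it.drug_id for it in ranked.items] == ["B", "C", "A"]

    def test_similarity_descending_with_lexicographic_ties(self, labeled_candidates):
        cands, ref = labeled_candidates
        scores = [loo("A", 0.40), loo("B", 0.40), loo("C", 0.10)]
        ranked = rank(cands, ref, "similarity", loo_scores=scores)
        assert [it.drug_id for it in ranked.items] == ["A", "B", "C"]

    def test_similarity_without_scores_rejected(self, labeled_candidates):
        cands, ref = labeled_candidates
        with pytest.raises(ValidationError):
            rank(cands, ref, "similarity")

    def test_unlabeled_candidate_rejected(self, labeled_candidates):
        _, ref = labeled_candidates
        cands = make_candidates("ade", [("ghost", 2.0, 0.01)])
        with pytest.raises(ValidationError, match="ghost"):
            rank(cands, ref, "p_value")


class TestPrecisionAtK:
    def test_six_of_ten(self):
        ranked = ranked_from_labels(["positive"] * 6 + ["negative"] * 4)
        assert precision_at_k(ranked, 10) == 0.6

    def test_all_positive_prefix(self):
        ranked = ranked_from_labels(["positive", "positive", "negative"])
        assert precision_at_k(ranked, 2) == 1.0

    def test_all_negative_prefix(self):
        ranked = ranked_from_labels(["negative", "negative", "positive"])
        assert precision_at_k(ranked, 2) == 0.0

    def test_full_length_equals_prevalence(self):
        labels = ["positive"] * 3 + ["negative"] * 7
        ranked = ranked_from_labels(labels)
        assert precision_at_k(ranked, 10) == 0.3

    def test_k_out_of_range(self):
        ranked = ranked_from_labels(["positive", "negative"])
        for bad in (0, 3):
            with pytest.raises(ValidationError):
                precision_at_k(ranked, bad)


class TestPRCurve:
    def test_perfect_ranking(self):
        ranked = ranked_from_labels(["positive"] * 3 + ["negative"] * 3)
        pts = pr_curve(ranked)
        assert pts[2] == (1.0, 1.0)  # precision 1.0 until full recall
        assert all(p == 1.0 for r, p in pts[:3])

    def test_inverted_ranking_ends_at_prevalence(self):
        ranked = ranked_from_labels(["negative"] * 3 + ["positive"] * 3)
        pts = pr_curve(ranked)
        assert pts[-1] == (1.0, 0.5)

    def test_hand_enumerated_three_candidates(self):
        # order P, N, P: cumulative (tp/i, tp/n_pos) per position
        ranked = ranked_from_labels(["positive", "negative", "positive"])
        assert pr_curve(ranked) == [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3)]

    def test_recall_non_decreasing(self, rng):
        labels = ["positive" if b else "negative" for b in rng.random(30) < 0.4]
        if "positive" not in labels:
            labels[0] = "positive"
        pts = pr_curve(ranked_from_labels(labels))
        recalls = [r for r, _ in pts]
        assert recalls == sorted(recalls)

    def test_zero_positives_rejected(self):
        with pytest.raises(ValidationError):
            pr_curve(ranked_from_labels(["negative", "negative"]))


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_all_tied_is_half(self):
        assert auroc([0.5] * 6, [True] * 3 + [False] * 3) == 0.5

    def test_three_of_four_concordant_pairs(self):
        # positives {0.9, 0.4} vs negatives {0.6, 0.1}: 3/4 concordant
        assert auroc([0.9, 0.4, 0.6, 0.1], [True, True, False, False]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([0.1, 0.2], [True, True])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1, allow_nan=False),
                st.booleans(),
            ),
            min_size=2,
            max_size=60,
        ).filter(lambda xs: any(l for _, l in xs) and any(not l for _, l in xs))
    )
    def test_rank_statistic_agrees_with_trapezoid(self, pairs):
        """Mann–Whitney and ROC-curve integration are the same number."""
        scores = [s for s, _ in pairs]
        labels = [l for _, l in pairs]
        assert auroc(scores, labels) == pytest.approx(
            auroc_trapezoid(scores, labels), abs=1e-12
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-5, 5, allow_nan=False), st.booleans()),
            min_size=2,
            max_size=40,
        ).filter(lambda xs: any(l for _, l in xs) and any(not l for _, l in xs))
    )
    def test_complement_identity(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [l for _, l in pairs]
        assert auroc(scores, labels) + auroc([-s for s in scores], labels) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.normal(size=30)
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_roc_points_start_and_end(self):
        pts = roc_points([0.9, 0.1], [True, False])
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)


class TestPAUROC:
    @pytest.fixture
    def setting(self):
        ref = make_reference(
            "ade",
            [("p1", "positive", "c"), ("p2", "positive", "c"),
             ("n1", "negative", "c"), ("n2", "negative", "c"),
             ("p3", "positive", "c"), ("n3", "negative", "c")],
        )
        cands = make_candidates(
            "ade",
            [("p1", 3.0, 0.01), ("p2", 2.0, 0.03), ("n1", 1.5, 0.02), ("n2", 1.1, 0.04),
             ("p3", 1.0, 0.5), ("n3", 1.0, 0.6)],
        )
        scores = {"p1": 0.5, "p2": 0.2, "n1": 0.3, "n2": 0.0, "p3": 0.9, "n3": 0.8}
        return cands, ref, scores

    def test_threshold_one_equals_full_auroc(self, setting):
        cands, ref, scores = setting
        vals = [scores[r.drug_id] for r in cands.rows]
        labs = [ref.label_of(r.drug_id) == "positive" for r in cands.rows]
        assert pauroc(cands, ref, scores, p_threshold=1.1) == auroc(vals, labs)

    def test_derived_subset_value(self, setting):
        # p<0.05 keeps p1,p2,n1,n2 with scores pos {0.5,0.2} / neg {0.3,0.0}:
        # 3 of 4 pairs concordant
        cands, ref, scores = setting
        assert pauroc(cands, ref, scores, p_threshold=0.05) == 0.75

    def test_perfectly_separated_subset(self, setting):
        cands, ref, _ = setting
        scores = {"p1": 0.9, "p2": 0.8, "n1": 0.2, "n2": 0.1, "p3": 0.0, "n3": 1.0}
        assert pauroc(cands, ref, scores, p_threshold=0.05) == 1.0

    def test_single_class_subset_reports_composition(self, setting):
        cands, ref, scores = setting
        with pytest.raises(ValidationError, match="positives"):
            pauroc(cands, ref, scores, p_threshold=0.015)  # only p1 remains


class TestEvaluate:
    def test_report_fields_consistent(self, labeled_candidates):
        cands, ref = labeled_candidates
        rep = evaluate(rank(cands, ref, "p_value"), ks=(1, 2, 3))
        assert rep.n_pos == 2 and rep.n_neg == 1
        assert rep.precision_at_k[3] == pytest.approx(2 / 3)
        assert len(rep.pr_points) == 3
        assert 0.0 <= rep.auroc <= 1.0

    def test_p_value_direction_respected(self):
        # smaller p must count as better in the report's AUROC
        ref = make_reference(
            "ade", [("a", "positive", "c"), ("b", "negative", "c")]
        )
        cands = make_candidates("ade", [("a", 2.0, 0.001), ("b", 1.0, 0.8)])
        rep = evaluate(rank(cands, ref, "p_value"), ks=(1,))
        assert rep.auroc == 1.0
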