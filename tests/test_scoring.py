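"""Similarity matrices, leave-one-out scoring, and the model facade."""

import itertools

import numpy as np
import pytest

from simsignal import (
    Measure,
    SimilarityMatrix,
    SimilarityModel,
    ValidationError,
    build_similarity_matrix,
    loo_score,
    score_candidates,
    tanimoto,
)
from simsignal.scoring import DIFFERENCE, POSITIVE_ONLY

from conftest import make_candidates, make_fp, make_matrix, make_reference


class TestSimilarityMatrix:
    def test_invariants_enforced(self, rng):
        s = rng.random((3, 3))  # asymmetric
        with pytest.raises(ValidationError):
            SimilarityMatrix(Measure.ADE, ("a", "b", "c"), s)

    def test_pair_count_matches_reference_standard_size(self):
        # 49 drugs give (49*49-49)/2 = 1,176 unordered pairs
        fps = [make_fp(f"d{i:02d}", [i, 100]) for i in range(49)]
        m = build_similarity_matrix(fps)
        assert m.n_pairs == 1176

    def test_identical_structures_score_one_off_diagonal(self):
        m = build_similarity_matrix([make_fp("a", [1, 2]), make_fp("b", [1, 2])])
        assert m.sim("a", "b") == 1.0

    def test_matches_elementwise_tanimoto(self):
        fps = [make_fp("a", [1, 2, 3]), make_fp("b", [2, 3, 4]), make_fp("c", [9])]
        m = build_similarity_matrix(fps)
        for fa, fb in itertools.combinations(fps, 2):
            assert m.sim(fa.drug_id, fb.drug_id) == tanimoto(fa, fb)

    def test_mixed_domains_rejected(self):
        fps = [make_fp("a", ["x"], Measure.ADE), make_fp("b", ["x"], Measure.TARGET)]
        with pytest.raises(ValidationError, match="mixed"):
            build_similarity_matrix(fps)

    def test_needs_two_drugs(self):
        with pytest.raises(ValidationError):
            build_similarity_matrix([make_fp("a", ["x"])])


class TestLOOScore:
    def test_published_worked_example(self, meloxicam_setting):
        """Best-positive 0.89, best-negative 0.49 -> difference 0.40."""
        probe, pos, neg, ref = meloxicam_setting
        m = build_similarity_matrix([probe, pos, neg])
        assert m.sim("meloxicam", "pos_ctrl") == pytest.approx(0.89)
        assert m.sim("meloxicam", "neg_ctrl") == pytest.approx(0.49)
        s = loo_score("meloxicam", m, ref, mode=DIFFERENCE)
        assert s.max_pos == pytest.approx(0.89)
        assert s.max_neg == pytest.approx(0.49)
        assert s.score == pytest.approx(0.40)
        assert s.best_pos_id == "pos_ctrl"

    def test_identical_to_both_groups_scores_zero(self):
        fps = [make_fp(d, [1, 2]) for d in ("x", "p", "n")]
        ref = make_reference("ade", [("p", "positive", "a"), ("n", "negative", "b"),
                                     ("x", "positive", "a")])
        s = loo_score("x", build_similarity_matrix(fps), ref)
        assert s.score == 0.0  # 1 - 1

    def test_positive_only_mode_is_max_pos(self, meloxicam_setting):
        probe, pos, neg, ref = meloxicam_setting
        m = build_similarity_matrix([probe, pos, neg])
        s = loo_score("meloxicam", m, ref, mode=POSITIVE_ONLY)
        assert s.score == s.max_pos == pytest.approx(0.89)

    def test_self_excluded_from_own_group(self):
        # the scored drug is a positive control; its self-similarity of 1
        # must not leak into max_pos
        fps = [make_fp("x", [1]), make_fp("p", [2]), make_fp("n", [3])]
        ref = make_reference("ade", [("x", "positive", "a"), ("p", "positive", "a"),
                                     ("n", "negative", "b")])
        s = loo_score("x", build_similarity_matrix(fps), ref)
        assert s.max_pos == 0.0 and s.best_pos_id == "p"

    def test_absent_drug_is_lookup_error(self, meloxicam_setting):
        probe, pos, neg, ref = meloxicam_setting
        m = build_similarity_matrix([probe, pos, neg])
        with pytest.raises(KeyError):
            loo_score("ghost", m, ref)

    def test_empty_comparator_group_is_error(self):
        fps = [make_fp("x", [1]), make_fp("p", [2])]
        m = build_similarity_matrix(fps)
        ref = make_reference("ade", [("p", "positive", "a"), ("x", "negative", "b")])
        # x is the only negative; after self-exclusion no negatives remain
        with pytest.raises(ValidationError, match="negative"):
            loo_score("x", m, ref)

    def test_invariant_to_reference_entry_order(self, rng):
        n = 8
        fps = [make_fp(f"d{i}", rng.choice(50, size=10, replace=False)) for i in range(n)]
        m = build_similarity_matrix(fps)
        rows = [(f"d{i}", "positive" if i % 2 else "negative", "c") for i in range(n)]
        ref_a = make_reference("ade", rows)
        ref_b = make_reference("ade", rows[::-1])
        for d in [f"d{i}" for i in range(n)]:
            assert loo_score(d, m, ref_a) == loo_score(d, m, ref_b)

    def test_difference_scores_bounded(self, rng):
        n = 10
        fps = [make_fp(f"d{i}", rng.choice(30, size=8, replace=False)) for i in range(n)]
        m = build_similarity_matrix(fps)
        rows = [(f"d{i}", "positive" if i < 5 else "negative", "c") for i in range(n)]
        ref = make_reference("ade", rows)
        for i in range(n):
            s = loo_score(f"d{i}", m, ref)
            assert -1.0 <= s.score <= 1.0
            sp = loo_score(f"d{i}", m, ref, mode=POSITIVE_ONLY)
            assert 0.0 <= sp.score <= 1.0


class TestScoreCandidates:
    @pytest.fixture
    def setting(self):
        ids = ["p1", "p2", "n1", "n2", "c1", "c2", "c3"]
        fps = [make_fp(d, [i, 10 + i]) for i, d in enumerate(ids)]
        m = build_similarity_matrix(fps)
        ref = make_reference(
            "ade",
            [("p1", "positive", "a"), ("p2", "positive", "a"),
             ("n1", "negative", "b"), ("n2", "negative", "b"),
             ("c1", "positive", "a"), ("c2", "negative", "b"), ("c3", "positive", "a")],
        )
        return m, ref

    def test_threshold_filter_semantics(self, setting):
        m, ref = setting
        cands = make_candidates("ade", [("c1", 2.0, 0.01), ("c2", 1.5, 0.2),
                                        ("c3", 3.0, 0.04)])
        rep = score_candidates(cands, m, ref, p_threshold=0.05)
        assert {s.drug_id for s in rep.scores} == {"c1", "c3"}
        assert rep.skipped == (("c2", 0.2),)

    def test_stricter_threshold_gives_nested_subset(self, setting):
        m, ref = setting
        cands = make_candidates("ade", [("c1", 2.0, 0.0001), ("c2", 1.5, 0.01),
                                        ("c3", 3.0, 0.04)])
        loose = {s.drug_id for s in score_candidates(cands, m, ref, 0.05).scores}
        strict = {s.drug_id for s in score_candidates(cands, m, ref, 0.0005).scores}
        assert strict <= loose

    def test_candidate_missing_from_matrix_reported_not_scored(self, setting):
        # e.g. a protein drug: no structural fingerprint, hence not in the matrix
        m, ref2 = setting
        ref = make_reference(
            "ade",
            [("p1", "positive", "a"), ("n1", "negative", "b"),
             ("interferon", "positive", "a")],
        )
        cands = make_candidates("ade", [("interferon", 4.0, 0.001)])
        rep = score_candidates(cands, m, ref, 0.05)
        assert rep.not_evaluable == ("interferon",)
        assert rep.scores == ()


class TestSeparationProperty:
    def test_tight_clusters_separate_perfectly(self):
        """Positives in one similarity cluster, negatives in another:
        every positive's difference score must exceed every negative's."""
        pos_fps = [make_fp(f"p{i}", [0, 1, 2, 3, 10 + i]) for i in range(5)]
        neg_fps = [make_fp(f"n{i}", [100, 101, 102, 103, 110 + i]) for i in range(5)]
        m = build_similarity_matrix(pos_fps + neg_fps)
        rows = [(f"p{i}", "positive", "a") for i in range(5)] + [
            (f"n{i}", "negative", "b") for i in range(5)
        ]
        ref = make_reference("ade", rows)
        pos_scores = [loo_score(f"p{i}", m, ref).score for i in range(5)]
        neg_scores = [loo_score(f"n{i}", m, ref).score for i in range(5)]
        assert min(pos_scores) > max(neg_scores)


class TestModelFacade:
    def test_fit_scores_every_evaluable_reference_drug(self):
        fps = [make_fp(f"d{i}", [i, i + 1, 50]) for i in range(6)]
        ref = make_reference(
            "ade", [(f"d{i}", "positive" if i < 3 else "negative", "c") for i in range(6)]
        )
        res = SimilarityModel.from_fingerprints(ref, fps).fit()
        assert {s.drug_id for s in res.loo_scores} == set(ref.drug_ids)
        assert 0.0 <= res.auroc <= 1.0

    def test_summary_mentions_key_facts(self):
        fps = [make_fp(f"d{i}", [i, 50]) for i in range(4)]
        ref = make_reference(
            "renal", [(f"d{i}", "positive" if i < 2 else "negative", "c") for i in range(4)]
        )
        text = SimilarityModel.from_fingerprints(ref, fps).fit().summary()
        assert "renal" in text and "AUROC" in text and "d0" in text

    def test_unfingerprinted_reference_drug_reported_not_evaluable(self):
        fps = [make_fp(f"d{i}", [i, 50]) for i in range(4)]
        ref = make_reference(
            "ade",
            [(f"d{i}", "positive" if i < 2 else "negative", "c") for i in range(4)]
            + [("lipase", "positive", "enzyme")],
        )
        res = SimilarityModel.from_fingerprints(ref, fps).fit()
        assert res.not_evaluable == ("lipase",)
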