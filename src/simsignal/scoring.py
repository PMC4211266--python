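"""Similarity matrices and leave-one-out scoring against a reference standard.

The central object is :class:`SimilarityModel`: a similarity-based model of
one adverse event, built from a reference standard (positive and negative
control drugs) and an all-pairs similarity matrix under one measure.
``fit()`` runs the leave-one-out evaluation — each drug is removed in turn
and scored by its maximum similarity to the remaining positive controls
minus its maximum similarity to the remaining negative controls — and
returns a :class:`SimilarityResults` carrying the per-drug scores, the
model's discrimination (AUROC of the scores against the control labels),
and methods to score external candidate drugs from a self-controlled
screen.

In ``positive_only`` mode the score is just the maximum similarity to the
positive controls; this avoids signal cancellation when pharmacologically
similar drugs sit in both control groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datamodel import (
    CandidateTable,
    Measure,
    ReferenceStandard,
    ValidationError,
)
from .fingerprints import BinaryFingerprint, tanimoto

logger = logging.getLogger(__name__)

DIFFERENCE = "difference"
POSITIVE_ONLY = "positive_only"
MODES = (DIFFERENCE, POSITIVE_ONLY)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric all-pairs similarity matrix in [0, 1] with unit diagonal."""

    measure: Measure
    drug_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        n = len(self.drug_ids)
        if len(set(self.drug_ids)) != n:
            raise ValidationError("drug_ids must be unique")
        if s.shape != (n, n):
            raise ValidationError(f"scores must be {n}x{n}, got {s.shape}")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValidationError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-9):
            raise ValidationError("similarity matrix must have unit diagonal")
        if s.min() < -1e-9 or s.max() > 1 + 1e-9:
            raise ValidationError("similarity scores must lie in [0, 1]")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_pairs(self) -> int:
        """Number of unordered off-diagonal pairs, n(n-1)/2."""
        n = self.n_drugs
        return n * (n - 1) // 2

    def index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"drug {drug_id!r} not in similarity matrix") from None

    def sim(self, a: str, b: str) -> float:
        return float(self.scores[self.index(a), self.index(b)])

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.drug_ids

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.drug_ids, columns=self.drug_ids)


def build_similarity_matrix(items: Sequence, measure: Measure | None = None) -> SimilarityMatrix:
    """Compute all n(n-1)/2 pairwise similarities.

    ``items`` is either a list of :class:`BinaryFingerprint` (Tanimoto) or a
    list of :class:`~simsignal.shape3d.ConformerSet` (3D shape similarity,
    ``measure`` defaults to SHAPE3D).
    """
    if len(items) < 2:
        raise ValidationError("need at least 2 drugs to build a similarity matrix")
    ids = [getattr(x, "drug_id") for x in items]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate drug ids among fingerprints")
    if isinstance(items[0], BinaryFingerprint):
        domains = {fp.domain for fp in items}
        if len(domains) != 1:
            raise ValidationError(
                f"mixed fingerprint domains: {sorted(d.value for d in domains)}"
            )
        inferred = domains.pop()
        if measure is not None and measure is not inferred:
            raise ValidationError(
                f"measure {measure.value} does not match fingerprint domain {inferred.value}"
            )
        measure = inferred
        pair_fn = tanimoto
    else:
        from .shape3d import shape_similarity

        measure = measure or Measure.SHAPE3D
        pair_fn = shape_similarity
    n = len(items)
    scores = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            scores[i, j] = scores[j, i] = pair_fn(items[i], items[j])
    return SimilarityMatrix(measure=measure, drug_ids=tuple(ids), scores=scores)


@dataclass(frozen=True)
class LOOScore:
    """Leave-one-out score of one drug against the reference standard.

    ``max_pos``/``max_neg`` are the maximum pairwise similarities to the
    positive and negative controls (the scored drug excluded from both);
    ``best_pos_id``/``best_neg_id`` name the most similar control in each
    group — the drug whose documented ADE profile rationalizes the signal.
    """

    drug_id: str
    measure: Measure
    mode: str
    max_pos: float
    best_pos_id: str
    max_neg: float
    best_neg_id: str
    score: float


def loo_score(
    drug_id: str,
    matrix: SimilarityMatrix,
    reference: ReferenceStandard,
    mode: str = DIFFERENCE,
) -> LOOScore:
    """Score one drug by maximum similarity against each control group.

    In ``difference`` mode the score is ``max_pos - max_neg`` (in [-1, 1]);
    in ``positive_only`` mode it is ``max_pos`` (in [0, 1]).
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    i = matrix.index(drug_id)  # KeyError if absent
    row = matrix.scores[i]

    def group_max(ids: Iterable[str], group: str) -> tuple[float, str]:
        pairs = [
            (float(row[matrix.index(d)]), d)
            for d in ids
            if d != drug_id and d in matrix
        ]
        if not pairs:
            raise ValidationError(
                f"no {group} comparators left for {drug_id!r} after self-exclusion"
            )
        # ties broken by lexicographically smallest comparator id
        return sorted(pairs, key=lambda t: (-t[0], t[1]))[0]

    max_pos, best_pos = group_max(reference.positives, "positive")
    max_neg, best_neg = group_max(reference.negatives, "negative")
    score = max_pos - max_neg if mode == DIFFERENCE else max_pos
    return LOOScore(
        drug_id=drug_id,
        measure=matrix.measure,
        mode=mode,
        max_pos=max_pos,
        best_pos_id=best_pos,
        max_neg=max_neg,
        best_neg_id=best_neg,
        score=score,
    )


@dataclass(frozen=True)
class ScoreReport:
    """Outcome of scoring a candidate table against a similarity model."""

    ade_name: str
    measure: Measure
    mode: str
    p_threshold: float
    scores: tuple[LOOScore, ...]
    skipped: tuple[tuple[str, float], ...]  # (drug_id, p_value) at/above threshold
    not_evaluable: tuple[str, ...]  # below threshold but absent from the matrix

    def score_of(self, drug_id: str) -> LOOScore:
        for s in self.scores:
            if s.drug_id == drug_id:
                return s
        raise KeyError(drug_id)


def score_candidates(
    candidates: CandidateTable,
    matrix: SimilarityMatrix,
    reference: ReferenceStandard,
    p_threshold: float = 0.05,
    mode: str = DIFFERENCE,
) -> ScoreReport:
    """LOO-score the candidates passing the p-value threshold.

    Candidates whose p-value is at or above the threshold are skipped.
    Candidates below the threshold but absent from the similarity matrix
    (protein drugs, drugs without annotations under this measure) cannot be
    evaluated by a similarity model and are reported separately.
    """
    scored: list[LOOScore] = []
    skipped: list[tuple[str, float]] = []
    not_evaluable: list[str] = []
    for r in candidates.rows:
        if not (r.p_value < p_threshold):
            skipped.append((r.drug_id, r.p_value))
            continue
        if r.drug_id not in matrix:
            not_evaluable.append(r.drug_id)
            logger.warning(
                "candidate %r (p=%.3g) passes the threshold but is not evaluable "
                "under measure %s",
                r.drug_id, r.p_value, matrix.measure.value,
            )
            continue
        scored.append(loo_score(r.drug_id, matrix, reference, mode=mode))
    return ScoreReport(
        ade_name=candidates.ade_name,
        measure=matrix.measure,
        mode=mode,
        p_threshold=p_threshold,
        scores=tuple(scored),
        skipped=tuple(skipped),
        not_evaluable=tuple(not_evaluable),
    )


class SimilarityModel:
    """Similarity-based model of one adverse event.

    Parameters
    ----------
    reference
        Positive/negative control drugs with pharmacological classes.
    matrix
        All-pairs similarity matrix under one measure, covering (at least)
        the reference drugs that are evaluable under that measure.
    mode
        ``"difference"`` (default) or ``"positive_only"``.
    """

    def __init__(
        self,
        reference: ReferenceStandard,
        matrix: SimilarityMatrix,
        mode: str = DIFFERENCE,
    ) -> None:
        if mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
        evaluable = [d for d in reference.drug_ids if d in matrix]
        if len(evaluable) < 3:
            raise ValidationError(
                "reference standard shares fewer than 3 drugs with the matrix"
            )
        self.reference = reference
        self.matrix = matrix
        self.mode = mode

    @classmethod
    def from_fingerprints(
        cls,
        reference: ReferenceStandard,
        fingerprints: Sequence[BinaryFingerprint],
        mode: str = DIFFERENCE,
    ) -> "SimilarityModel":
        missing = [d for d in reference.drug_ids if d not in {f.drug_id for f in fingerprints}]
        if missing:
            logger.warning(
                "%d reference drugs lack fingerprints and are not evaluable: %s",
                len(missing), missing,
            )
        return cls(reference, build_similarity_matrix(list(fingerprints)), mode=mode)

    def fit(self) -> "SimilarityResults":
        """Run the leave-one-out evaluation over the reference standard."""
        scores = []
        not_evaluable = []
        for d in self.reference.drug_ids:
            if d not in self.matrix:
                not_evaluable.append(d)
                continue
            scores.append(loo_score(d, self.matrix, self.reference, mode=self.mode))
        return SimilarityResults(self, tuple(scores), tuple(not_evaluable))


class SimilarityResults:
    """Fitted leave-one-out scores of a :class:`SimilarityModel`."""

    def __init__(
        self,
        model: SimilarityModel,
        loo_scores: tuple[LOOScore, ...],
        not_evaluable: tuple[str, ...],
    ) -> None:
        self.model = model
        self.loo_scores = loo_scores
        self.not_evaluable = not_evaluable

    @property
    def reference(self) -> ReferenceStandard:
        return self.model.reference

    def frame(self):
        """Per-drug scores and labels as a DataFrame."""
        import pandas as pd

        ref = self.reference
        return pd.DataFrame(
            {
                "drug_id": [s.drug_id for s in self.loo_scores],
                "label": [ref.label_of(s.drug_id) for s in self.loo_scores],
                "max_pos": [s.max_pos for s in self.loo_scores],
                "best_pos_id": [s.best_pos_id for s in self.loo_scores],
                "max_neg": [s.max_neg for s in self.loo_scores],
                "best_neg_id": [s.best_neg_id for s in self.loo_scores],
                "score": [s.score for s in self.loo_scores],
            }
        )

    @property
    def auroc(self) -> float:
        """Discrimination of the LOO scores between control groups."""
        from .evaluation import auroc

        ref = self.reference
        labels = [ref.label_of(s.drug_id) == "positive" for s in self.loo_scores]
        return auroc([s.score for s in self.loo_scores], labels)

    def score_candidates(
        self, candidates: CandidateTable, p_threshold: float = 0.05
    ) -> ScoreReport:
        return score_candidates(
            candidates, self.model.matrix, self.reference, p_threshold, self.model.mode
        )

    def summary(self) -> str:
        ref = self.reference
        df = self.frame().sort_values("score", ascending=False)
        lines = [
            "Similarity model: leave-one-out results",
            "=" * 55,
            f"Adverse event:        {ref.ade_name}",
            f"Measure:              {self.model.matrix.measure.value}",
            f"Mode:                 {self.model.mode}",
            f"Reference drugs:      {len(ref)} "
            f"({len(ref.positives)} positive / {len(ref.negatives)} negative)",
            f"Not evaluable:        {len(self.not_evaluable)}",
            f"LOO AUROC:            {self.auroc:.3f}",
            "-" * 55,
            f"{'drug_id':<14}{'label':<10}{'max_pos':>8}{'max_neg':>8}{'score':>8}",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r.drug_id:<14}{r.label:<10}{r.max_pos:>8.3f}{r.max_neg:>8.3f}{r.score:>8.3f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SimilarityResults {self.reference.ade_name!r} "
            f"measure={self.model.matrix.measure.value} n={len(self.loo_scores)}>"
        )
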