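"""Ranking of ADE candidates and evaluation of rankings.

Candidates can be ranked by the self-controlled screen's p-value
(ascending), its relative risk (descending), or by similarity score
(descending). Rankings are evaluated against the reference-standard labels
with precision@k (TP/(TP+FP) within the top k), precision–recall curves,
and AUROC. The *pAUROC* is the AUROC computed only on the subset of
candidates passing the screen's p-value threshold — a full AUROC on a
restricted set, not a partial area over an FPR range. Recall denominators
likewise count only positives within the thresholded set.

AUROC uses the Mann–Whitney rank-statistic formulation (ties get half
credit): the probability that a random positive outranks a random negative.
``auroc_trapezoid`` integrates the empirical ROC curve instead; the two
agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .datamodel import (
    CandidateTable,
    POSITIVE,
    ReferenceStandard,
    ValidationError,
)
from .scoring import LOOScore

METHOD_P_VALUE = "p_value"
METHOD_RR = "rr"
METHOD_SIMILARITY = "similarity"


@dataclass(frozen=True)
class RankedItem:
    drug_id: str
    sort_key: float
    label: str


@dataclass(frozen=True)
class RankedList:
    """Deterministic total order of labeled candidates under one method."""

    ade_name: str
    method: str
    items: tuple[RankedItem, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def labels(self) -> tuple[bool, ...]:
        return tuple(it.label == POSITIVE for it in self.items)

    def __len__(self) -> int:
        return len(self.items)


def rank(
    candidates: CandidateTable,
    reference: ReferenceStandard,
    method: str,
    loo_scores: Sequence[LOOScore] | None = None,
    p_threshold: float | None = None,
) -> RankedList:
    """Rank candidates by ``p_value``, ``rr``, or ``similarity``.

    p-values sort ascending, RR and similarity scores descending; ties are
    broken by drug id (lexicographic), making the order deterministic.
    When ``method="similarity"``, only drugs present in ``loo_scores`` are
    ranked (the evaluable set). An optional ``p_threshold`` restricts every
    method to the screen-selected subset first.
    """
    rows = candidates.rows if p_threshold is None else candidates.filtered_rows(p_threshold)
    for r in rows:
        if r.drug_id not in reference:
            raise ValidationError(
                f"candidate {r.drug_id!r} has no label in reference standard "
                f"{reference.ade_name!r}"
            )
    if method == METHOD_P_VALUE:
        keyed = [(r.p_value, r.drug_id) for r in rows]
        keyed.sort(key=lambda t: (t[0], t[1]))
    elif method == METHOD_RR:
        keyed = [(r.rr, r.drug_id) for r in rows]
        keyed.sort(key=lambda t: (-t[0], t[1]))
    elif method == METHOD_SIMILARITY:
        if loo_scores is None:
            raise ValidationError("similarity ranking requires loo_scores")
        by_id = {s.drug_id: s.score for s in loo_scores}
        keep = [r.drug_id for r in rows if r.drug_id in by_id]
        keyed = [(by_id[d], d) for d in keep]
        keyed.sort(key=lambda t: (-t[0], t[1]))
    else:
        raise ValidationError(f"unknown ranking method {method!r}")
    items = tuple(
        RankedItem(drug_id=d, sort_key=k, label=reference.label_of(d)) for k, d in keyed
    )
    return RankedList(ade_name=candidates.ade_name, method=method, items=items)


def precision_at_k(ranked: RankedList, k: int) -> float:
    """Fraction of positives among the first k ranked candidates."""
    if not (1 <= k <= len(ranked)):
        raise ValidationError(f"k must be in [1, {len(ranked)}], got {k}")
    labels = ranked.labels[:k]
    return sum(labels) / k


def pr_curve(ranked: RankedList) -> list[tuple[float, float]]:
    """One (recall, precision) point per rank position.

    The recall denominator is the number of positives within the ranked
    (already threshold-selected) set. No interpolation is applied.
    """
    labels = ranked.labels
    n_pos = sum(labels)
    if n_pos == 0:
        raise ValidationError("cannot compute a PR curve with zero positives")
    points = []
    tp = 0
    for i, lab in enumerate(labels, start=1):
        tp += lab
        points.append((tp / n_pos, tp / i))
    return points


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability a random positive scores above a random negative.

    Mann–Whitney formulation on midranks; tied scores contribute half
    credit. Equivalent to trapezoidal integration of the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"AUROC needs both classes; got {n_pos} positives and {n_neg} negatives"
        )
    ranks = rankdata(scores)  # midranks handle ties with half credit
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[bool]) -> list[tuple[float, float]]:
    """Empirical ROC curve as (FPR, TPR) points, one per distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(scores)):
        tp += int(labels[i])
        fp += int(not labels[i])
        if i + 1 == len(scores) or scores[i + 1] != scores[i]:
            pts.append((fp / n_neg, tp / n_pos))
    return pts


def auroc_trapezoid(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUROC by trapezoidal integration of the empirical ROC curve."""
    pts = roc_points(scores, labels)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


def pauroc(
    candidates: CandidateTable,
    reference: ReferenceStandard,
    scores: Mapping[str, float] | Sequence[LOOScore],
    p_threshold: float = 0.05,
) -> float:
    """AUROC restricted to candidates with p-value below the threshold."""
    if not isinstance(scores, Mapping):
        scores = {s.drug_id: s.score for s in scores}
    rows = [r for r in candidates.filtered_rows(p_threshold) if r.drug_id in scores]
    vals = [scores[r.drug_id] for r in rows]
    labs = [reference.label_of(r.drug_id) == POSITIVE for r in rows]
    n_pos, n_neg = sum(labs), len(labs) - sum(labs)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"thresholded subset (p < {p_threshold}) is single-class: "
            f"{n_pos} positives, {n_neg} negatives among {len(labs)} candidates"
        )
    return auroc(vals, labs)


@dataclass(frozen=True)
class EvaluationReport:
    """Precision/PR/AUROC summary of one ranking."""

    ade_name: str
    method: str
    precision_at_k: dict[int, float]
    pr_points: list[tuple[float, float]]
    auroc: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "ade_name": self.ade_name,
            "method": self.method,
            "precision_at_k": {str(k): v for k, v in self.precision_at_k.items()},
            "pr_points": [list(p) for p in self.pr_points],
            "auroc": self.auroc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def evaluate(ranked: RankedList, ks: Sequence[int] = (5, 10, 20)) -> EvaluationReport:
    """Build the standard report for one ranking.

    The AUROC here is computed over the ranked set itself — when the ranked
    list was built from a p-thresholded candidate table, it is the pAUROC.
    Ranking direction is respected: p-values are negated so that a "better"
    candidate always carries a larger score.
    """
    labels = list(ranked.labels)
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    sign = -1.0 if ranked.method == METHOD_P_VALUE else 1.0
    scores = [sign * it.sort_key for it in ranked.items]
    return EvaluationReport(
        ade_name=ranked.ade_name,
        method=ranked.method,
        precision_at_k={k: precision_at_k(ranked, k) for k in ks if 1 <= k <= len(ranked)},
        pr_points=pr_curve(ranked),
        auroc=auroc(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def plot_pr_curves(reports: Sequence[EvaluationReport], path) -> None:
    """Precision–recall curves for several methods on one axes (one ADE)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for rep in reports:
        xs = [p[0] for p in rep.pr_points]
        ys = [p[1] for p in rep.pr_points]
        ax.plot(xs, ys, marker="o", markersize=3, label=rep.method)
    ax.set_xlabel("recall (within selected candidates)")
    ax.set_ylabel("precision")
    ax.set_title(reports[0].ade_name if reports else "")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
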