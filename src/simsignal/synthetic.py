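"""Synthetic reference standards and self-controlled candidate tables.

Real inputs to this pipeline — curated reference standards, SIDER/DrugBank
annotation extracts, and candidate tables mined from a claims database —
are licensed or proprietary. This module generates structurally faithful
stand-ins so every downstream stage is testable:

* ``simulate_reference_standard`` partitions drugs into pharmacological
  classes, gives each class a core feature set plus globally shared
  background features and per-drug private features (sized in closed form
  so realized within/between-class Jaccard similarities match the
  configured targets), and assigns positive/negative labels with a
  configurable class–label correlation.
* ``simulate_candidate_table`` emulates a self-controlled screen at the
  per-drug aggregate level: event counts in exposed vs unexposed
  person-time are Poisson, true positives carry an elevated incidence-rate
  ratio, RR is the exposed/unexposed rate ratio, and the p-value is an
  exact binomial test of the exposed-event fraction against the
  person-time-expected fraction. This is deliberately simpler than a full
  conditional-likelihood self-controlled case series; it produces (RR, p)
  tables with the right joint behaviour for method evaluation.
* ``end_to_end_demo`` wires simulate -> threshold -> LOO-score -> rank ->
  evaluate into one call.

All randomness flows from the config seed through one named generator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .datamodel import (
    CandidateRow,
    CandidateTable,
    Measure,
    NEGATIVE,
    POSITIVE,
    RefEntry,
    ReferenceStandard,
    ValidationError,
)
from .evaluation import (
    METHOD_P_VALUE,
    METHOD_RR,
    METHOD_SIMILARITY,
    EvaluationReport,
    evaluate,
    rank,
)
from .fingerprints import BinaryFingerprint
from .scoring import DIFFERENCE, ScoreReport, SimilarityMatrix, SimilarityModel

__all__ = [
    "SyntheticConfig",
    "simulate_reference_standard",
    "simulate_rr_pvalue",
    "simulate_candidate_table",
    "end_to_end_demo",
    "DemoResult",
    "fixture_config",
    "random_similarity_matrix",
    "random_class_labels",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("renal", "liver", "mi", "gi_ulcer")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic adverse-event outcome.

    Person-time fields are aggregate totals per drug (abstract units); the
    defaults put the screen in a moderate-power regime (roughly seven
    expected events per drug, detection power ~0.6 for a rate ratio of 4)
    — the regime where re-ranking by similarity has room to help.
    """

    ade_name: str = "synthetic_ade"
    n_positive: int = 25
    n_negative: int = 24
    n_classes: int = 7
    class_sizes: tuple[int, ...] | None = None
    n_features: int = 4192
    within_class_jaccard: float = 0.7
    between_class_jaccard: float = 0.1
    n_private_features: int = 5
    label_class_correlation: float = 0.9
    irr_positive: float = 4.0
    exposed_time: float = 60.0
    unexposed_time: float = 300.0
    baseline_rate: float = 0.02
    n_subjects: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_sizes is not None:
            object.__setattr__(self, "class_sizes", tuple(self.class_sizes))
            if sum(self.class_sizes) != self.n_drugs:
                raise ValidationError(
                    f"class_sizes sum to {sum(self.class_sizes)}, expected "
                    f"{self.n_drugs} (= n_positive + n_negative)"
                )
        for name in ("n_positive", "n_negative", "n_classes", "n_features", "n_subjects"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (self.within_class_jaccard > self.between_class_jaccard):
            raise ValidationError(
                "within_class_jaccard must exceed between_class_jaccard "
                f"({self.within_class_jaccard} <= {self.between_class_jaccard})"
            )
        if not (0.0 <= self.label_class_correlation <= 1.0):
            raise ValidationError("label_class_correlation must be in [0, 1]")
        if self.irr_positive < 1.0:
            raise ValidationError("irr_positive must be >= 1")
        if self.exposed_time <= 0 or self.unexposed_time <= 0:
            raise ValidationError("person-time must be positive")
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be positive")

    @property
    def n_drugs(self) -> int:
        return self.n_positive + self.n_negative

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        if "class_sizes" in d and d["class_sizes"] is not None:
            d = dict(d, class_sizes=tuple(d["class_sizes"]))
        return cls(**d)


def _feature_block_sizes(cfg: SyntheticConfig) -> tuple[int, int]:
    """Common-block and class-core sizes matching the Jaccard targets.

    With every drug holding g shared background features, its class core of
    c features, and d unique private features, pairwise Jaccard is
    (g+c)/(g+c+2d) within a class and g/(g+2c+2d) between classes. Solving
    for (g, c) given d and the two targets gives the block sizes (rounded,
    floored at 1).
    """
    d = cfg.n_private_features
    jw, jb = cfg.within_class_jaccard, cfg.between_class_jaccard
    gc = jw * 2 * d / (1.0 - jw)  # g + c
    g = jb * (2 * gc + 2 * d) / (1.0 + jb)
    c = gc - g
    g_i, c_i = max(1, round(g)), max(1, round(c))
    return g_i, c_i


def _class_sizes(cfg: SyntheticConfig) -> tuple[int, ...]:
    if cfg.class_sizes is not None:
        return cfg.class_sizes
    n, k = cfg.n_drugs, cfg.n_classes
    base = n // k
    sizes = [base + (1 if i < n % k else 0) for i in range(k)]
    return tuple(sizes)


def _assign_labels(
    classes: np.ndarray, n_positive: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Labels correlated with class membership; exact positive count.

    Classes are filled with positives largest-first until n_positive is
    exhausted, then k = (1-rho) * n_pos*n_neg/n random positive<->negative
    swaps degrade the correlation: rho=1 keeps classes label-pure (up to
    the class straddling the count boundary), rho=0 matches the expected
    class overlap of fully random labels.
    """
    n = len(classes)
    n_negative = n - n_positive
    ks = np.arange(classes.max() + 1)
    counts = np.array([np.sum(classes == k) for k in ks])
    order = ks[np.argsort(-counts, kind="stable")]
    lab = np.zeros(n, dtype=bool)
    left = n_positive
    for k in order:
        idx = np.where(classes == k)[0]
        take = min(left, len(idx))
        lab[idx[:take]] = True
        left -= take
        if left == 0:
            break
    nswap = int(round((1.0 - rho) * n_positive * n_negative / n))
    pos = rng.permutation(np.where(lab)[0])
    neg = rng.permutation(np.where(~lab)[0])
    for a, b in zip(pos[:nswap], neg[:nswap]):
        lab[a], lab[b] = False, True
    return lab


def simulate_reference_standard(
    cfg: SyntheticConfig,
) -> tuple[ReferenceStandard, list[BinaryFingerprint]]:
    """Generate a labeled, class-structured drug set with fingerprints.

    Deterministic per seed. Realized within-class pairwise Tanimoto
    similarities concentrate near ``within_class_jaccard`` and between-class
    ones near ``between_class_jaccard``.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = _class_sizes(cfg)
    g, c = _feature_block_sizes(cfg)
    n = cfg.n_drugs
    classes = np.repeat(np.arange(len(sizes)), sizes)

    # feature universe layout: [0, g) common block, then per-class cores;
    # private features drawn from the remaining universe without replacement
    n_core_total = g + c * len(sizes)
    if n_core_total + n * cfg.n_private_features > cfg.n_features:
        raise ValidationError(
            f"n_features={cfg.n_features} too small for {len(sizes)} classes "
            f"(needs >= {n_core_total + n * cfg.n_private_features})"
        )
    common = frozenset(range(g))
    cores = [frozenset(range(g + k * c, g + (k + 1) * c)) for k in range(len(sizes))]
    private_pool = rng.permutation(np.arange(n_core_total, cfg.n_features))
    labels = _assign_labels(classes, cfg.n_positive, cfg.label_class_correlation, rng)

    width = max(3, len(str(n)))
    entries = []
    fingerprints = []
    for i in range(n):
        drug_id = f"D{i + 1:0{width}d}"
        priv = frozenset(
            int(x) for x in private_pool[i * cfg.n_private_features : (i + 1) * cfg.n_private_features]
        )
        keys = common | cores[int(classes[i])] | priv
        fingerprints.append(
            BinaryFingerprint(drug_id=drug_id, domain=Measure.MACCS2D, keys=keys)
        )
        entries.append(
            RefEntry(
                drug_id=drug_id,
                label=POSITIVE if labels[i] else NEGATIVE,
                pharm_class=f"class{int(classes[i]) + 1:02d}",
            )
        )
    return ReferenceStandard(ade_name=cfg.ade_name, entries=tuple(entries)), fingerprints


def simulate_rr_pvalue(
    rng: np.random.Generator,
    exposed_time: float,
    unexposed_time: float,
    baseline_rate: float,
    rate_ratio: float = 1.0,
) -> tuple[float, float]:
    """One drug's (RR, p) from simulated exposed/unexposed event counts.

    Events are Poisson with rate ``baseline_rate`` (times ``rate_ratio``
    during exposure). RR is the exposed/unexposed event-rate ratio with a
    0.5 continuity correction applied to both counts whenever either is
    zero; with no events at all, RR = 1 and p = 1 (no information). The
    p-value is the exact binomial test of the exposed-event count among all
    events against the person-time-expected exposed fraction.
    """
    if exposed_time <= 0 or unexposed_time <= 0:
        raise ValidationError("person-time must be positive")
    y_e = int(rng.poisson(baseline_rate * rate_ratio * exposed_time))
    y_u = int(rng.poisson(baseline_rate * unexposed_time))
    total = y_e + y_u
    if total == 0:
        return 1.0, 1.0
    if y_e == 0 or y_u == 0:
        a, b = y_e + 0.5, y_u + 0.5
    else:
        a, b = float(y_e), float(y_u)
    rr = (a / exposed_time) / (b / unexposed_time)
    p = binomtest(y_e, total, exposed_time / (exposed_time + unexposed_time)).pvalue
    return rr, float(p)


def simulate_candidate_table(
    reference: ReferenceStandard,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> CandidateTable:
    """Self-controlled screen output for every drug in the reference.

    Positive controls carry ``irr_positive``; negatives the null rate
    ratio 1. Seeded from ``cfg.seed + 1`` by default so the table varies
    independently of the reference-standard draw.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for e in reference.entries:
        ratio = cfg.irr_positive if e.label == POSITIVE else 1.0
        rr, p = simulate_rr_pvalue(
            rng, cfg.exposed_time, cfg.unexposed_time, cfg.baseline_rate, ratio
        )
        rows.append(CandidateRow(drug_id=e.drug_id, rr=rr, p_value=p))
    return CandidateTable(ade_name=reference.ade_name, rows=tuple(rows))


@dataclass(frozen=True)
class DemoResult:
    """All artifacts of one simulated end-to-end run."""

    config: SyntheticConfig
    reference: ReferenceStandard
    fingerprints: tuple[BinaryFingerprint, ...]
    matrix: SimilarityMatrix
    candidates: CandidateTable
    score_report: ScoreReport
    reports: dict[str, EvaluationReport]


def end_to_end_demo(
    cfg: SyntheticConfig, p_threshold: float = 0.05, mode: str = DIFFERENCE
) -> DemoResult:
    """simulate -> threshold -> LOO-score -> rank by p/RR/similarity -> evaluate.

    Evaluation reports are produced per ranking method on the thresholded
    candidate subset (so each report's AUROC is the pAUROC); methods whose
    subset is single-class are omitted from the report dict.
    """
    reference, fingerprints = simulate_reference_standard(cfg)
    model = SimilarityModel.from_fingerprints(reference, fingerprints, mode=mode)
    results = model.fit()
    candidates = simulate_candidate_table(reference, cfg)
    score_report = results.score_candidates(candidates, p_threshold=p_threshold)
    reports: dict[str, EvaluationReport] = {}
    for method in (METHOD_P_VALUE, METHOD_RR, METHOD_SIMILARITY):
        ranked = rank(
            candidates,
            reference,
            method,
            loo_scores=score_report.scores,
            p_threshold=p_threshold,
        )
        if len(ranked) == 0:
            continue
        try:
            reports[method] = evaluate(ranked)
        except ValidationError:
            continue  # thresholded subset single-class or empty of positives
    return DemoResult(
        config=cfg,
        reference=reference,
        fingerprints=tuple(fingerprints),
        matrix=model.matrix,
        candidates=candidates,
        score_report=score_report,
        reports=reports,
    )


def fixture_config(name: str, **overrides) -> SyntheticConfig:
    """Load one of the packaged outcome configs (renal, liver, mi, gi_ulcer)."""
    import yaml

    if name not in FIXTURE_NAMES:
        raise ValidationError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = importlib.resources.files("simsignal") / "configs" / f"{name}.yaml"
    cfg = yaml.safe_load(ref.read_text(encoding="utf-8"))
    cfg.update(overrides)
    return SyntheticConfig.from_dict(cfg)


def random_similarity_matrix(
    n_drugs: int, rng: np.random.Generator, measure: Measure = Measure.MACCS2D
) -> SimilarityMatrix:
    """Symmetric matrix of i.i.d. uniform scores — similarity carries no
    class information. Used for permutation-test calibration."""
    if n_drugs < 2:
        raise ValidationError("need at least 2 drugs")
    s = np.zeros((n_drugs, n_drugs))
    iu, ju = np.triu_indices(n_drugs, k=1)
    vals = rng.random(len(iu))
    s[iu, ju] = vals
    s[ju, iu] = vals
    np.fill_diagonal(s, 1.0)
    width = max(3, len(str(n_drugs)))
    ids = tuple(f"D{i + 1:0{width}d}" for i in range(n_drugs))
    return SimilarityMatrix(measure=measure, drug_ids=ids, scores=s)


def random_class_labels(
    drug_ids: Sequence[str], n_classes: int, rng: np.random.Generator
) -> dict[str, str]:
    """Uniformly random class assignment, independent of any similarity."""
    draws = rng.integers(0, n_classes, len(drug_ids))
    return {d: f"class{int(k) + 1:02d}" for d, k in zip(drug_ids, draws)}
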