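"""Core domain types for similarity-based ADE signal prioritization.

The unit of analysis is a drug; every similarity measure is computed over
pairs of drugs. A *reference standard* labels drugs as positive controls
(known to cause the adverse event) or negative controls (believed not to),
each with a pharmacological class. A *candidate table* carries the output of
an upstream self-controlled screen: per-drug relative risk and p-value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ValidationError",
    "StructureError",
    "Measure",
    "ANNOTATION_DOMAINS",
    "Drug",
    "AnnotationSet",
    "RefEntry",
    "ReferenceStandard",
    "CandidateRow",
    "CandidateTable",
    "POSITIVE",
    "NEGATIVE",
    "LABELS",
]


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class StructureError(ValueError):
    """A molecular structure could not be parsed or processed."""


class Measure(str, enum.Enum):
    """Similarity measure / fingerprint feature domain."""

    MACCS2D = "maccs2d"
    SHAPE3D = "shape3d"
    ADE = "ade"
    TARGET = "target"
    ATC = "atc"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Domains whose fingerprints come from annotation tables rather than structure.
ANNOTATION_DOMAINS = frozenset({Measure.ADE, Measure.TARGET, Measure.ATC})

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = frozenset({POSITIVE, NEGATIVE})


@dataclass(frozen=True)
class Drug:
    """A drug with optional structure.

    Protein drugs (``is_protein=True``) are excluded from structural
    fingerprinting: structure-based similarity is not meaningful at protein
    size, so they are reported as not evaluable by the 2D/3D measures.
    """

    drug_id: str
    name: str = ""
    smiles: str | None = None
    is_protein: bool = False

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")


@dataclass(frozen=True)
class AnnotationSet:
    """Set of vocabulary terms attached to one drug in one domain.

    For TARGET the caller is expected to have deduplicated terms across
    target/enzyme/transporter/carrier sources and across organisms; the set
    semantics here collapse exact duplicates regardless.
    """

    drug_id: str
    domain: Measure
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if self.domain not in ANNOTATION_DOMAINS:
            raise ValidationError(
                f"annotation domain must be one of {sorted(d.value for d in ANNOTATION_DOMAINS)}, "
                f"got {self.domain!r}"
            )
        object.__setattr__(self, "terms", frozenset(self.terms))


@dataclass(frozen=True)
class RefEntry:
    drug_id: str
    label: str
    pharm_class: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"label for {self.drug_id!r} must be 'positive' or 'negative', got {self.label!r}"
            )
        if not self.pharm_class:
            raise ValidationError(f"pharm_class for {self.drug_id!r} must be non-empty")


@dataclass(frozen=True)
class ReferenceStandard:
    """Per-ADE labeled drug set: positive and negative controls with classes."""

    ade_name: str
    entries: tuple[RefEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        seen: dict[str, int] = {}
        for e in self.entries:
            if e.drug_id in seen:
                raise ValidationError(
                    f"drug {e.drug_id!r} appears more than once in reference standard "
                    f"{self.ade_name!r}"
                )
            seen[e.drug_id] = 1
        if not self.positives or not self.negatives:
            raise ValidationError(
                f"reference standard {self.ade_name!r} needs at least one positive "
                f"and one negative control"
            )

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(e.drug_id for e in self.entries)

    @property
    def positives(self) -> tuple[str, ...]:
        return tuple(e.drug_id for e in self.entries if e.label == POSITIVE)

    @property
    def negatives(self) -> tuple[str, ...]:
        return tuple(e.drug_id for e in self.entries if e.label == NEGATIVE)

    @property
    def classes(self) -> Mapping[str, str]:
        return {e.drug_id: e.pharm_class for e in self.entries}

    def label_of(self, drug_id: str) -> str:
        for e in self.entries:
            if e.drug_id == drug_id:
                return e.label
        raise KeyError(f"drug {drug_id!r} not in reference standard {self.ade_name!r}")

    def __contains__(self, drug_id: str) -> bool:
        return any(e.drug_id == drug_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CandidateRow:
    drug_id: str
    rr: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.rr > 0):
            raise ValidationError(f"rr for {self.drug_id!r} must be > 0, got {self.rr}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(
                f"p_value for {self.drug_id!r} must be in [0, 1], got {self.p_value}"
            )


@dataclass(frozen=True)
class CandidateTable:
    """Per-drug signal statistics (RR, p-value) from a self-controlled screen."""

    ade_name: str
    rows: tuple[CandidateRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        ids = [r.drug_id for r in self.rows]
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        if dupes:
            raise ValidationError(f"duplicate candidate drug ids: {dupes}")

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(r.drug_id for r in self.rows)

    def row_of(self, drug_id: str) -> CandidateRow:
        for r in self.rows:
            if r.drug_id == drug_id:
                return r
        raise KeyError(f"drug {drug_id!r} not in candidate table {self.ade_name!r}")

    def filtered_rows(self, p_threshold: float) -> tuple[CandidateRow, ...]:
        """Rows with p-value strictly below the threshold (the screen's cut)."""
        return tuple(r for r in self.rows if r.p_value < p_threshold)

    def __len__(self) -> int:
        return len(self.rows)
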