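"""Binary fingerprints and the Tanimoto coefficient.

Four fingerprint families share one representation — a sparse set of present
feature keys:

* ``MACCS2D`` — the public 166-key MACCS structural dictionary (e.g. key 11
  flags four-membered rings, key 163 six-membered rings), computed with
  RDKit. Historical MDL implementations differ on a few keys, so Tanimoto
  values can deviate from other toolkits in the second decimal.
* ``ADE`` — adverse-event terms attached to the drug (SIDER-style). When a
  fingerprint is built for scoring against a particular adverse event, that
  event and its related terms are excluded so the outcome under study does
  not contribute to its own similarity signal.
* ``TARGET`` — protein targets (targets, enzymes, transporters, carriers
  merged; organisms collapsed upstream).
* ``ATC`` — Anatomical Therapeutic Chemical codes, optionally expanded to
  all hierarchical prefixes (levels 1–5) so that overlap at the therapeutic
  level contributes to similarity.

The Tanimoto coefficient between fingerprints A and B is
``N_AB / (N_A + N_B - N_AB)`` where ``N_A``/``N_B`` are the key counts and
``N_AB`` the count of shared keys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .datamodel import AnnotationSet, Drug, Measure, StructureError, ValidationError

logger = logging.getLogger(__name__)

MACCS_NUM_KEYS = 166

#: Seed exclusion lists per adverse-event outcome: the outcome itself plus
#: related vocabulary variants. The renal list follows the worked example for
#: acute renal failure; the other three are starting points that users extend
#: with their own related-term curation.
DEFAULT_ADE_EXCLUSIONS: dict[str, frozenset[str]] = {
    "acute renal failure": frozenset(
        {"renal failure acute", "acute renal insufficiency", "shutdown renal"}
    ),
    "acute liver failure": frozenset(
        {"hepatic failure", "hepatic failure acute", "liver failure acute"}
    ),
    "acute myocardial infarction": frozenset(
        {"myocardial infarction", "infarction myocardial acute", "myocardial infarct"}
    ),
    "upper gastrointestinal ulcer": frozenset(
        {"gastrointestinal ulcer", "ulcer gastrointestinal", "peptic ulcer", "gastric ulcer"}
    ),
}


@dataclass(frozen=True)
class BinaryFingerprint:
    """Sparse set of present feature keys in a named feature domain.

    Keys are integers (1-based MACCS key indices) for ``MACCS2D`` and
    vocabulary term strings for the annotation domains.
    """

    drug_id: str
    domain: Measure
    keys: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "keys", frozenset(self.keys))
        if self.domain is Measure.MACCS2D and len(self.keys) > MACCS_NUM_KEYS:
            raise ValidationError(
                f"MACCS fingerprint for {self.drug_id!r} has {len(self.keys)} keys; "
                f"the dictionary defines only {MACCS_NUM_KEYS}"
            )

    def __len__(self) -> int:
        return len(self.keys)


def maccs_fingerprint(drug: Drug) -> BinaryFingerprint:
    """Compute the 166-key MACCS structural fingerprint of a drug.

    Protein drugs are rejected: structural keys are not meaningful at
    protein size. Keys are the 1-based indices of set bits.
    """
    if drug.is_protein:
        raise ValidationError(
            f"drug {drug.drug_id!r} is flagged as a protein and cannot be "
            f"structurally fingerprinted"
        )
    if not drug.smiles:
        raise StructureError(f"drug {drug.drug_id!r} has no structure")
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None:
        raise StructureError(
            f"could not parse structure for drug {drug.drug_id!r}: {drug.smiles!r}"
        )
    # RDKit returns a 167-bit vector whose bit 0 is unused padding.
    bits = MACCSkeys.GenMACCSKeys(mol)
    return BinaryFingerprint(
        drug_id=drug.drug_id, domain=Measure.MACCS2D, keys=frozenset(bits.GetOnBits())
    )


def expand_atc_prefixes(codes: Iterable[str]) -> frozenset[str]:
    """Expand full ATC codes to all hierarchical prefixes (levels 1–5).

    ``"A10BA02"`` becomes ``{"A", "A10", "A10B", "A10BA", "A10BA02"}``.
    Codes shorter than seven characters are expanded down to whatever levels
    they cover.
    """
    out: set[str] = set()
    for code in codes:
        code = code.strip().upper()
        for cut in (1, 3, 4, 5, 7):
            if len(code) >= cut:
                out.add(code[:cut])
        if 0 < len(code) < 7 and len(code) not in (1, 3, 4, 5):
            out.add(code)
    return frozenset(out)


def annotation_fingerprint(
    annotations: AnnotationSet,
    exclusion_terms: Iterable[str] = (),
    *,
    expand_atc: bool = True,
    atc_override: Mapping[str, str] | None = None,
) -> BinaryFingerprint:
    """Build a fingerprint from a drug's annotation terms.

    ``exclusion_terms`` removes the outcome under study and its related
    terms (ADE domain); it is normally empty for TARGET and ATC. For ATC,
    multi-code drugs keep all codes unless ``atc_override`` maps the drug to
    a single curated code, and codes are expanded to hierarchical prefixes
    when ``expand_atc`` is on.
    """
    terms = set(annotations.terms)
    if annotations.domain is Measure.ATC:
        if atc_override and annotations.drug_id in atc_override:
            terms = {atc_override[annotations.drug_id]}
        if expand_atc:
            terms = set(expand_atc_prefixes(terms))
    keys = frozenset(terms) - frozenset(exclusion_terms)
    if not keys:
        logger.warning(
            "fingerprint for drug %r in domain %s is empty after exclusions",
            annotations.drug_id,
            annotations.domain.value,
        )
    return BinaryFingerprint(drug_id=annotations.drug_id, domain=annotations.domain, keys=keys)


def tanimoto(a: BinaryFingerprint, b: BinaryFingerprint) -> float:
    """Tanimoto coefficient ``N_AB / (N_A + N_B - N_AB)`` in [0, 1].

    Two empty fingerprints give 0 by convention (and a log warning): an
    absence of information is not evidence of similarity.
    """
    if a.domain is not b.domain:
        raise ValidationError(
            f"cannot compare fingerprints across domains: {a.domain.value} vs {b.domain.value}"
        )
    n_ab = len(a.keys & b.keys)
    denom = len(a.keys) + len(b.keys) - n_ab
    if denom == 0:
        logger.warning(
            "Tanimoto between two empty fingerprints (%r, %r) defined as 0",
            a.drug_id,
            b.drug_id,
        )
        return 0.0
    return n_ab / denom
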