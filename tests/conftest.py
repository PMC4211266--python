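import numpy as np
import pytest

from simsignal import (
    BinaryFingerprint,
    CandidateRow,
    CandidateTable,
    Drug,
    Measure,
    RefEntry,
    ReferenceStandard,
    SimilarityMatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def benzene():
    return Drug(drug_id="benzene", smiles="c1ccccc1")


@pytest.fixture
def cyclobutane():
    return Drug(drug_id="cyclobutane", smiles="C1CCC1")


@pytest.fixture
def methane():
    return Drug(drug_id="methane", smiles="C")


def make_fp(drug_id, keys, domain=Measure.ADE):
    """Fingerprint with string keys unless the domain is MACCS2D."""
    if domain is Measure.MACCS2D:
        keys = frozenset(int(k) for k in keys)
    else:
        keys = frozenset(str(k) for k in keys)
    return BinaryFingerprint(drug_id=drug_id, domain=domain, keys=keys)


def make_matrix(ids, pair_scores, measure=Measure.MACCS2D):
    """Build a SimilarityMatrix from a dict {(id_a, id_b): score}."""
    n = len(ids)
    s = np.eye(n)
    index = {d: i for i, d in enumerate(ids)}
    for (a, b), v in pair_scores.items():
        s[index[a], index[b]] = s[index[b], index[a]] = v
    return SimilarityMatrix(measure=measure, drug_ids=tuple(ids), scores=s)


def make_reference(ade, rows):
    """rows: list of (drug_id, label, pharm_class) tuples."""
    return ReferenceStandard(
        ade_name=ade, entries=tuple(RefEntry(*row) for row in rows)
    )


def make_candidates(ade, rows):
    """rows: list of (drug_id, rr, p_value)."""
    return CandidateTable(ade_name=ade, rows=tuple(CandidateRow(*r) for r in rows))


@pytest.fixture
def meloxicam_setting():
    """Minimal reference standard reproducing the published worked example:
    the scored drug's best positive-control similarity is 0.89 and its best
    negative-control similarity is 0.49 (exact set-overlap construction:
    89/100 and 49/100)."""
    probe = make_fp("meloxicam", range(100))
    pos = make_fp("pos_ctrl", range(89))
    neg = make_fp("neg_ctrl", range(49))
    ref = make_reference(
        "acute renal failure",
        [
            ("pos_ctrl", "positive", "nsaid"),
            ("neg_ctrl", "negative", "other"),
            ("meloxicam", "positive", "nsaid"),
        ],
    )
    return probe, pos, neg, ref
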