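"""Readers and writers for the package's plain-text interchange formats.

Formats
-------
SMILES table   TSV: ``drug_id<TAB>smiles[<TAB>name[<TAB>is_protein]]``; ``#`` comments.
SDF            structures via RDKit; the molecule title is the drug id.
Annotations    TSV: ``drug_id<TAB>term``, one pair per line.
Reference CSV  header ``ade,drug_id,label,pharm_class``.
Candidate CSV  header ``ade,drug_id,rr,p_value``.
Fingerprints   TSV: ``drug_id<TAB>domain<TAB>comma,joined,sorted,keys``.
Matrix         TSV with a ``# measure: <name>`` first line, then a header
               row/column of drug ids.

All readers are order-preserving and deterministic; all writers produce
files the corresponding reader round-trips without loss.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .datamodel import (
    AnnotationSet,
    CandidateRow,
    CandidateTable,
    Drug,
    Measure,
    RefEntry,
    ReferenceStandard,
    ValidationError,
)

logger = logging.getLogger(__name__)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


def read_smiles_table(path: str | Path) -> list[Drug]:
    """Read a ``.smi``-style TSV of drug structures."""
    path = Path(path)
    drugs: list[Drug] = []
    lines_by_id: dict[str, list[int]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'id<TAB>smiles[<TAB>name[<TAB>is_protein]]', "
                    f"got {line!r}"
                )
            drug_id, smiles = parts[0].strip(), parts[1].strip()
            name = parts[2].strip() if len(parts) > 2 else ""
            flag = parts[3].strip().lower() if len(parts) > 3 else ""
            if flag not in _TRUE | _FALSE:
                raise ValidationError(
                    f"{path}:{lineno}: is_protein must be boolean-like, got {parts[3]!r}"
                )
            lines_by_id.setdefault(drug_id, []).append(lineno)
            drugs.append(
                Drug(drug_id=drug_id, name=name, smiles=smiles or None, is_protein=flag in _TRUE)
            )
    dupes = {d: ls for d, ls in lines_by_id.items() if len(ls) > 1}
    if dupes:
        desc = "; ".join(f"{d!r} on lines {ls}" for d, ls in sorted(dupes.items()))
        raise ValidationError(f"{path}: duplicate drug ids: {desc}")
    if not drugs:
        logger.warning("%s: no data lines found, returning empty drug list", path)
    return drugs


def write_smiles_table(path: str | Path, drugs: Iterable[Drug]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in drugs:
            fh.write(
                f"{d.drug_id}\t{d.smiles or ''}\t{d.name}\t{'1' if d.is_protein else '0'}\n"
            )


def read_sdf(path: str | Path) -> list[Drug]:
    """Read structures from an SDF file; molecule titles become drug ids."""
    from rdkit import Chem

    drugs: list[Drug] = []
    seen: set[str] = set()
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: record %d could not be parsed, skipped", path, i + 1)
            continue
        drug_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not drug_id:
            raise ValidationError(f"{path}: record {i + 1} has no title to use as drug id")
        if drug_id in seen:
            raise ValidationError(f"{path}: duplicate drug id {drug_id!r}")
        seen.add(drug_id)
        drugs.append(Drug(drug_id=drug_id, smiles=Chem.MolToSmiles(mol)))
    return drugs


def read_annotations(path: str | Path, domain: Measure | str) -> list[AnnotationSet]:
    """Read a ``drug_id<TAB>term`` TSV, grouping rows into per-drug term sets.

    Drugs with no rows are simply absent from the output: a drug with no
    annotation information is *not evaluable* under the measure, which is
    different from having an empty (all-zero) fingerprint.
    """
    try:
        domain = Measure(domain)
    except ValueError as exc:
        raise ValidationError(f"unknown annotation domain {domain!r}") from exc
    if domain in (Measure.MACCS2D, Measure.SHAPE3D):
        raise ValidationError(f"{domain.value!r} is a structural measure, not an annotation domain")
    path = Path(path)
    terms: dict[str, set[str]] = {}
    order: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValidationError(
                    f"{path}:{lineno}: expected 'drug_id<TAB>term', got {line!r}"
                )
            drug_id, term = parts[0].strip(), parts[1].strip()
            if drug_id not in terms:
                terms[drug_id] = set()
                order.append(drug_id)
            terms[drug_id].add(term)
    return [AnnotationSet(drug_id=d, domain=domain, terms=frozenset(terms[d])) for d in order]


def write_annotations(path: str | Path, annotations: Iterable[AnnotationSet]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for ann in annotations:
            for term in sorted(ann.terms):
                fh.write(f"{ann.drug_id}\t{term}\n")


def _read_csv_rows(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise ValidationError(
                f"{path}: expected CSV header with columns {list(required)}, "
                f"got {reader.fieldnames}"
            )
        return list(reader)


def read_reference_standard(path: str | Path) -> ReferenceStandard:
    path = Path(path)
    rows = _read_csv_rows(path, ("ade", "drug_id", "label", "pharm_class"))
    if not rows:
        raise ValidationError(f"{path}: reference standard has no rows")
    ades = {r["ade"] for r in rows}
    if len(ades) != 1:
        raise ValidationError(f"{path}: expected a single ADE per file, found {sorted(ades)}")
    entries = []
    for i, r in enumerate(rows, start=2):
        try:
            entries.append(RefEntry(r["drug_id"], r["label"], r["pharm_class"]))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return ReferenceStandard(ade_name=ades.pop(), entries=tuple(entries))


def write_reference_standard(path: str | Path, ref: ReferenceStandard) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ade", "drug_id", "label", "pharm_class"])
        for e in ref.entries:
            writer.writerow([ref.ade_name, e.drug_id, e.label, e.pharm_class])


def read_candidates(path: str | Path) -> CandidateTable:
    path = Path(path)
    rows = _read_csv_rows(path, ("ade", "drug_id", "rr", "p_value"))
    if not rows:
        raise ValidationError(f"{path}: candidate table has no rows")
    ades = {r["ade"] for r in rows}
    if len(ades) != 1:
        raise ValidationError(f"{path}: expected a single ADE per file, found {sorted(ades)}")
    out = []
    for i, r in enumerate(rows, start=2):
        try:
            out.append(CandidateRow(r["drug_id"], float(r["rr"]), float(r["p_value"])))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return CandidateTable(ade_name=ades.pop(), rows=tuple(out))


def write_candidates(path: str | Path, table: CandidateTable) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ade", "drug_id", "rr", "p_value"])
        for r in table.rows:
            writer.writerow([table.ade_name, r.drug_id, repr(r.rr), repr(r.p_value)])


def read_fingerprints(path: str | Path):
    """Read cached fingerprints from TSV. Keys for MACCS2D are ints."""
    from .fingerprints import BinaryFingerprint

    path = Path(path)
    out = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'drug_id<TAB>domain<TAB>keys', got {line!r}"
                )
            drug_id, domain_s, keys_s = parts
            domain = Measure(domain_s)
            raw_keys = [k for k in keys_s.split(",") if k != ""]
            keys: frozenset = (
                frozenset(int(k) for k in raw_keys)
                if domain is Measure.MACCS2D
                else frozenset(raw_keys)
            )
            out.append(BinaryFingerprint(drug_id=drug_id, domain=domain, keys=keys))
    return out


def write_fingerprints(path: str | Path, fingerprints) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for fp in fingerprints:
            keys = ",".join(str(k) for k in sorted(fp.keys))
            fh.write(f"{fp.drug_id}\t{fp.domain.value}\t{keys}\n")


def read_matrix(path: str | Path):
    from .scoring import SimilarityMatrix

    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# measure:"):
            raise ValidationError(f"{path}: missing '# measure: <name>' first line")
        measure = Measure(first.split(":", 1)[1].strip())
        header = fh.readline().rstrip("\n").split("\t")
        drug_ids = header[1:]
        rows = []
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            rows.append([float(x) for x in parts[1:]])
    scores = np.array(rows, dtype=float)
    return SimilarityMatrix(measure=measure, drug_ids=tuple(drug_ids), scores=scores)


def write_matrix(path: str | Path, matrix) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# measure: {matrix.measure.value}\n")
        fh.write("drug_id\t" + "\t".join(matrix.drug_ids) + "\n")
        for i, d in enumerate(matrix.drug_ids):
            fh.write(d + "\t" + "\t".join(repr(float(x)) for x in matrix.scores[i]) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML run/simulation configuration."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg
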