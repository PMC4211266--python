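"""Pharmacophore-feature-weighted 3D shape similarity.

An open conformer-based analogue of commercial shape screening: each drug is
embedded into up to ``max_conformers`` 3D conformers (ETKDG), minimized with
MMFF94 (UFF fallback), and the lowest-energy conformer is kept as the
alignment template. Similarity between two drugs is the maximum, over
conformers of one aligned onto the template of the other (both directions),
of a Gaussian volume-overlap score restricted to pharmacophore features of
matching type (donor, acceptor, aromatic, hydrophobe, charged), normalized
Tanimoto-style:

    sim = V_AB / (V_AA + V_BB - V_AB)

where ``V_XY`` sums the Gaussian overlap ``exp(-gamma * d^2)`` over all
feature pairs of identical type between X and Y. The score lies in [0, 1],
equals 1 for a molecule against itself, and is invariant to rigid-body
transforms of either input because alignment precedes scoring. Molecules
sharing no feature type score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Drug, StructureError, ValidationError

logger = logging.getLogger(__name__)

#: Gaussian decay of the feature-overlap kernel, 1/Angstrom^2. Chosen so two
#: features ~1 A apart still overlap strongly (0.74) while features >3 A
#: apart contribute little (<0.07).
GAUSS_GAMMA = 0.3

_FEATURE_FAMILIES = (
    "Donor",
    "Acceptor",
    "Aromatic",
    "Hydrophobe",
    "LumpedHydrophobe",
    "PosIonizable",
    "NegIonizable",
)

_factory = None


def _feature_factory():
    global _factory
    if _factory is None:
        import os

        from rdkit import RDConfig
        from rdkit.Chem import ChemicalFeatures

        _factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
    return _factory


@dataclass
class ConformerSet:
    """Embedded conformers of one drug; ``template_conf_id`` marks the
    global-minimum-energy conformer used as the alignment template."""

    drug_id: str
    mol: object  # rdkit Mol with explicit hydrogens and >=1 conformer
    energies: np.ndarray
    template_conf_id: int

    def __post_init__(self) -> None:
        n = self.mol.GetNumConformers()
        if n < 1:
            raise ValidationError(f"ConformerSet for {self.drug_id!r} has no conformers")
        if len(self.energies) != n:
            raise ValidationError("energies length must match conformer count")

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def features(self, conf_id: int) -> list[tuple[str, np.ndarray]]:
        """Typed pharmacophore feature centroids for one conformer."""
        factory = _feature_factory()
        out = []
        for f in factory.GetFeaturesForMol(self.mol, confId=conf_id):
            if f.GetFamily() in _FEATURE_FAMILIES:
                p = f.GetPos(conf_id)
                out.append((f.GetFamily(), np.array([p.x, p.y, p.z])))
        return out


def prepare_and_embed(drug: Drug, max_conformers: int = 500, seed: int = 0) -> ConformerSet:
    """Embed a drug into 3D conformers and pick the minimum-energy template.

    Deterministic for a fixed seed. Near-duplicate conformers are pruned by
    RMSD during embedding, so rigid molecules end up with a single conformer.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if drug.is_protein:
        raise ValidationError(f"drug {drug.drug_id!r} is a protein; no 3D embedding")
    if not drug.smiles:
        raise StructureError(f"drug {drug.drug_id!r} has no structure")
    if max_conformers < 1:
        raise ValidationError("max_conformers must be >= 1")
    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None:
        raise StructureError(f"could not parse structure for drug {drug.drug_id!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.pruneRmsThresh = 0.5
    conf_ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=max_conformers, params=params))
    if not conf_ids:
        raise StructureError(f"3D embedding failed for drug {drug.drug_id!r}")
    energies = _minimize(mol, conf_ids)
    template = conf_ids[int(np.argmin(energies))]
    return ConformerSet(
        drug_id=drug.drug_id, mol=mol, energies=np.asarray(energies, dtype=float),
        template_conf_id=template,
    )


def _minimize(mol, conf_ids) -> list[float]:
    from rdkit.Chem import AllChem

    energies = []
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
        ok = all(e == e for _, e in results)  # NaN check
    except Exception:  # pragma: no cover - MMFF setup failure
        ok = False
        results = []
    if ok and results:
        energies = [e for _, e in results]
    else:  # pragma: no cover - exercised only for MMFF-unsupported chemistry
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
        energies = [e for _, e in results]
    if len(energies) != len(conf_ids):
        energies = energies[: len(conf_ids)]
    return energies


def _typed_overlap(
    feats_a: list[tuple[str, np.ndarray]], feats_b: list[tuple[str, np.ndarray]]
) -> float:
    total = 0.0
    for fam_a, pos_a in feats_a:
        for fam_b, pos_b in feats_b:
            if fam_a == fam_b:
                d2 = float(np.sum((pos_a - pos_b) ** 2))
                total += np.exp(-GAUSS_GAMMA * d2)
    return total


def _best_alignment_overlap(ref: ConformerSet, probe: ConformerSet) -> float:
    """Max typed overlap of any probe conformer aligned onto ref's template."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    ref_feats = ref.features(ref.template_conf_id)
    if not ref_feats:
        return 0.0
    # align a copy: O3A moves the probe's conformer coordinates in place
    probe_mol = Chem.Mol(probe.mol)
    moved = ConformerSet(
        drug_id=probe.drug_id,
        mol=probe_mol,
        energies=probe.energies,
        template_conf_id=probe.template_conf_id,
    )
    best = 0.0
    for conf in probe_mol.GetConformers():
        cid = conf.GetId()
        try:
            o3a = AllChem.GetO3A(
                probe_mol, ref.mol, prbCid=cid, refCid=ref.template_conf_id
            )
            o3a.Align()
        except Exception:
            try:
                o3a = AllChem.GetCrippenO3A(
                    probe_mol, ref.mol, prbCid=cid, refCid=ref.template_conf_id
                )
                o3a.Align()
            except Exception:
                logger.debug(
                    "alignment failed for %s conformer %d onto %s; using raw coordinates",
                    probe.drug_id, cid, ref.drug_id,
                )
        best = max(best, _typed_overlap(ref_feats, moved.features(cid)))
    return best


def shape_similarity(a: ConformerSet, b: ConformerSet) -> float:
    """Feature-typed volume-overlap Tanimoto between two drugs, in [0, 1].

    Maximizes over conformers of each drug aligned onto the other's
    minimum-energy template; the two directions are combined by max, making
    the score exactly symmetric.
    """
    feats_a = a.features(a.template_conf_id)
    feats_b = b.features(b.template_conf_id)
    v_aa = _typed_overlap(feats_a, feats_a)
    v_bb = _typed_overlap(feats_b, feats_b)
    if v_aa == 0.0 or v_bb == 0.0:
        logger.warning(
            "drug %r or %r has no pharmacophore features; shape similarity is 0",
            a.drug_id, b.drug_id,
        )
        return 0.0
    if not set(f for f, _ in feats_a) & set(f for f, _ in feats_b):
        return 0.0
    v_ab = max(_best_alignment_overlap(a, b), _best_alignment_overlap(b, a))
    denom = v_aa + v_bb - v_ab
    if denom <= 0:  # numerically impossible for distinct sets; guard anyway
        return 1.0
    return float(min(1.0, max(0.0, v_ab / denom)))
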