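# Methods

## Model

`simsignal` implements similarity-based re-ranking of adverse-drug-event
(ADE) candidates. The object of inference is not a parametric model but a
nearest-labeled-neighbour scorer: given a reference standard of positive
controls (drugs that cause the outcome) and negative controls (drugs that
do not), a candidate drug's score is

    score(d) = max_pos(d) − max_neg(d)

where `max_pos(d)` is the largest pairwise similarity between *d* and any
positive control other than *d* itself, and `max_neg(d)` likewise over the
negative controls. The leave-one-out convention removes only the scored
drug from its own comparator group; all other reference drugs contribute
regardless of whether they are themselves under evaluation. The score lies
in [−1, 1]. In *positive-only* mode the score is `max_pos(d)` alone
(range [0, 1]); this is the recommended mode when the reference standard
places pharmacologically similar drugs in both control groups, where the
difference would cancel genuine signal.

The assumptions are those of any guilt-by-association method: that the
similarity measure is informative about the causal mechanism, and that
the reference standard's labels are correct. Both degrade gracefully —
an uninformative measure yields scores unrelated to the labels (AUROC
≈ 0.5), not systematic error.

### Similarity measures

All measures reduce to the Tanimoto coefficient
`N_AB / (N_A + N_B − N_AB)` over sparse binary fingerprints, except the
3D measure:

* **MACCS 2D** (166 public structural keys, computed with RDKit).
  Historical MDL implementations differ on a handful of key definitions,
  so Tanimoto values may differ from other toolkits in the second decimal;
  the packaged checks on published drug pairs therefore use a ±0.02
  tolerance.
* **ADE terms.** When fingerprints are built for a particular outcome,
  the outcome term and user-supplied related terms are excluded
  (`DEFAULT_ADE_EXCLUSIONS` seeds the four shipped outcomes; the renal
  list is the canonical worked example, the other three are starting
  points, because related-term curation is inherently manual).
* **Targets.** Deduplication across target/enzyme/transporter/carrier
  sources and across organisms is the data supplier's responsibility;
  the reader collapses exact duplicates.
* **ATC.** Codes are optionally (default on) expanded to all hierarchical
  prefixes, so two drugs sharing a therapeutic subgroup overlap even when
  their full codes differ. Multi-code drugs keep all codes unless a
  curated single-code override is supplied.
* **3D shape.** Conformers are embedded with ETKDG (deterministic per
  seed, near-duplicates pruned at 0.5 Å RMSD), minimized with MMFF94
  (UFF fallback), and the global-minimum-energy conformer of each drug is
  its alignment template. Similarity is a feature-typed Gaussian
  volume-overlap Tanimoto: pharmacophore features (donor, acceptor,
  aromatic, hydrophobe, charged) contribute `exp(−γ d²)` overlap only to
  features of identical type, with γ = 0.3 Å⁻²; each drug's conformers are
  aligned (O3A) onto the other's template and the best overlap in either
  direction is used, making the score exactly symmetric, rigid-motion
  invariant, 1 on self, and 0 for molecules sharing no feature type.
  This is an open-source analogue of commercial pharmacophore shape
  screening, not a numerical reproduction of it: published 3D scores are
  not comparable targets.

Two empty fingerprints have Tanimoto 0 by convention (logged): absence of
annotation must not masquerade as perfect similarity. Drugs with *no*
annotation record under a measure (and protein drugs, for the structural
measures) are excluded from that measure's matrix entirely and reported as
"not evaluable" rather than given empty fingerprints — scarce information
is a reason to abstain, not a zero-similarity observation.

### Evaluation

Rankings by similarity score (descending), screen p-value (ascending) and
relative risk (descending) are made deterministic by lexicographic drug-id
tie-breaks. Metrics: precision@k; per-rank precision–recall points with
the recall denominator restricted to positives inside the thresholded
candidate set; AUROC via the Mann–Whitney rank statistic with midrank tie
handling (the package also integrates the empirical ROC curve
trapezoidally; the two routes agree to 1e-12 and are cross-checked against
scikit-learn in the tests). The pAUROC is a *full* AUROC computed on the
subset of candidates with screen p-value below the threshold — not a
partial area over an FPR range. Candidate p-value thresholds are strict
inequalities (p < 0.05, p < 0.0005).

### Class enrichment

For one similarity matrix and a class label per drug: take the top-N
unordered pairs (ties at the boundary resolved by score desc, then pair
ids ascending, cut at exactly N), count same-class pairs, and compare with
the urn expectation N·K/M (K same-class pairs among M = n(n−1)/2).
Significance comes from permuting class labels over drugs — preserving
class sizes, the matrix, and the top-N pair set — with the add-one
corrected tail probability (x+1)/(B+1), default 10,000 permutations, seed
mandatory. The hypergeometric tail P(X ≥ observed) is reported alongside
as an analytic cross-check; it treats the N pairs as exchangeable draws,
which ignores the shared-drug dependence among pairs, so the two p-values
agree in magnitude but not exactly.

## Synthetic data generator

The real inputs (curated reference standards, SIDER/DrugBank extracts,
claims-database screens) are licensed, so the generator emulates their
structure:

* **Fingerprints with class geometry.** Each drug holds g globally shared
  features, its class core of c features, and d = 5 private features.
  Pairwise Jaccard is then (g+c)/(g+c+2d) within a class and g/(g+2c+2d)
  between classes; (g, c) are solved from the configured targets (defaults
  0.7 within / 0.1 between, giving g = 5, c = 18). Private features are
  drawn from a 4,192-feature universe (the scale of a side-effect
  vocabulary). Realized means land within a few hundredths of the targets.
* **Labels.** Positives are filled class-by-class (largest first), then
  k = (1−ρ)·n_pos·n_neg/n random positive↔negative swaps: ρ = 1 keeps
  classes label-pure, ρ = 0 matches the expected class overlap of fully
  random labels, and positive/negative counts are exact throughout.
* **Self-controlled screen.** Per drug, events in exposed and unexposed
  person-time are Poisson; positives carry an incidence-rate ratio (IRR),
  negatives rate ratio 1. RR is the exposed/unexposed rate ratio with a
  0.5 continuity correction on both counts whenever either is zero (both
  zero: RR = 1, p = 1 — the corrected ratio would otherwise equal the
  person-time ratio, a spurious signal from no events). The p-value is an
  exact binomial test of the exposed-event count among all events against
  the person-time-expected fraction. This per-drug aggregate stand-in
  deliberately replaces the full conditional-likelihood self-controlled
  case series, which needs person-level data.

**Default study conditions.** The shipped outcome configs (renal, liver,
mi, gi_ulcer) use reference standards of 45–51 drugs whose class-size
profiles mix one large class, several mid-size classes and many singletons
(the renal profile yields exactly 74 same-class pairs among 1,176);
within/between-class Jaccard 0.7/0.1; class–label correlation 0.9; IRR 4;
and aggregate person-time 60 exposed / 300 unexposed units at baseline
rate 0.02 events per unit — about seven expected events per drug and
detection power ≈ 0.6 at IRR 4. That moderate-power regime is the
scientifically interesting one: the screen's p-value ordering is good but
imperfect, which is exactly when similarity re-ranking has room to help.

**What the generator does not emulate:** real chemistry (synthetic
"MACCS-style" fingerprints are abstract feature sets, not substructure
keys of actual molecules), annotation sparsity and bias of knowledge
bases, confounding by co-medication or indication, and within-person
dependency structure of claims data. Passing tests therefore demonstrate
correctness and calibration of the machinery under controlled conditions,
not field performance on real pharmacovigilance data.

## Numerical and design choices

* AUROC ties get half credit (Mann–Whitney midranks).
* `max` over an empty comparator group after self-exclusion is an error,
  never a silent 0 — silent zeros would bias difference scores.
* Every similarity matrix is validated on construction (symmetry, unit
  diagonal, [0, 1] range); serialization uses full `repr` precision so
  round-trips are exact.
* All stochastic stages take explicit seeds and draw from a single named
  generator; no global RNG state. CLI data outputs contain no timestamps,
  so equal-seed runs are byte-identical.
* Exact binomial tests are conservative at sparse counts: at the default
  screen conditions (~7 events/drug) the null rejection rate at α = 0.05
  is about 0.02. The type-I calibration suite therefore runs at
  claims-scale person-time (2,000/10,000 units, ~240 events per drug),
  where discreteness is negligible and the empirical rate is ≈ 0.04 —
  matching the scale of the data sources such screens actually run on.
* The permutation-calibration suite draws matrices of 90–130 drugs with
  2–5 classes and top-N of 200–300. At reference-standard scale (49
  drugs, top 50) the same-class count has a handful of achievable values
  and its permutation p-value is necessarily lumpy-superuniform — a
  property of any correct implementation of a discrete permutation test,
  not an implementation defect — so uniformity is verified where the
  statistic is finely resolved.
* Problem sizes in the heavier suites (100 signal replicates, ~1,200 null
  replicates, 200 calibration matrices × 1,000 permutations, 1,000
  simulated null drugs) were chosen to give comfortable statistical
  resolution for each check while keeping a full run on one CPU in the
  tens of seconds.

## Known limitations

* MACCS key dialects differ across toolkits; cross-toolkit Tanimoto
  values can differ by ~0.01–0.02.
* The 3D score depends on conformer coverage and O3A alignment quality;
  for very flexible molecules the maximum over embedded conformers is a
  lower bound on the attainable overlap.
* Candidates absent from the reference standard can be similarity-scored
  but not evaluated (no label); the evaluation layer rejects them
  explicitly rather than guessing.
* The urn expectation and hypergeometric p-value ignore shared-drug
  dependence among pairs; the permutation test is the primary inference.
* The generator's ρ = 1 "label-pure classes" guarantee holds exactly only
  when no class straddles the positive-count boundary; with the shipped
  configs the boundary falls between classes.
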