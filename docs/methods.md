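# Methods

## Problem and scope

`bindres` predicts, per residue, whether an amino acid in an alpha-helical
membrane-protein chain binds a ligand, using sequence-derived features
only. The package covers the full chain of steps: deriving ground-truth
labels from structures, encoding residues into window feature vectors,
fitting and applying a Gaussian Naïve Bayes classifier, and
leave-one-protein-out (LOPO) evaluation. Dataset curation (culling
membrane-protein structures, redundancy filtering) and running PSI-BLAST
are out of scope: the package parses PSI-BLAST's ASCII PSSM output but
expects users working with real data to generate profiles themselves.

## Ground-truth labels from structures

A **ligand** is any het group in a coordinate file that is neither water
(HOH/DOD/WAT) nor a polymer residue, and that has at least one atom within
the contact cutoff of at least one protein atom. Residue *i* is **binding**
when the minimum over all (residue-*i* atom, ligand atom) Euclidean
distances is *strictly below* the cutoff, 4.5 Å by default. Choices worth
stating explicitly:

- **Strict `<` versus `≤`**: the default is strict; an `inclusive=True`
  flag switches to `≤` for users who read "within 4.5 Å" as closed. At
  crystallographic coordinate precision the difference is cosmetic but the
  boundary behaviour is pinned by tests (a pair at exactly 4.5 Å does not
  count).
- **All deposited atoms participate**, hydrogens included when present.
- **No additive blacklist**: ions and crystallisation additives count as
  ligands, since any exclusion list is a curation decision better made by
  the caller.
- **Alternate locations**: only the highest-occupancy conformer of each
  disordered atom is kept (ties broken toward altloc 'A').
- **Modified polymer residues** (MSE and a few phosphorylated forms) stay
  in the chain with sequence code `X`; their atoms still participate in
  distance checks. Other het groups in chain context are ligands.
- **Indexing**: residues are re-indexed 0-based and contiguous per chain;
  the deposited author numbering is retained as metadata only.
- Only the first model of multi-model files is read by default.

Contact queries use a k-d tree (`scipy.spatial.cKDTree`) over ligand
atoms. The test suite holds the tree-based labels to *exact* equality with
an exhaustive all-pairs distance scan on every fixture, so the
acceleration is an implementation detail, not an approximation.

## Encodings

Residue *t* is represented by the concatenated per-residue vectors of a
window of `s = 2k + 1` positions centred on *t*; `k = 2` by default, the
setting that historically performed best for this task among k = 1…7. Per-residue
representations:

- **PSSM**: the residue's 20 log-odds scores, columns ordered
  `ARNDCQEGHILKMFPSTWYV` everywhere in the package.
- **BLOSUM62**: the residue's row of the canonical half-bit matrix (taken
  from biopython's `substitution_matrices`); `X` maps to the zero vector.
- **Properties**: a 20×P table, default P = 48 — 28 literature scales
  (Kyte–Doolittle and Eisenberg/Fauchère–Pliska/Hopp–Woods/Wimley–White
  hydrophobicity-family scales, Grantham polarity, molecular weight,
  charge, pI, volume, max ASA, Chou–Fasman helix/sheet/turn propensities,
  heavy-atom and side-chain atom counts, H-bond donor/acceptor counts,
  rotatable bonds, and chemical-class indicators) plus the 20
  residue-identity indicators. The exact membership of a "48 important
  properties" set is not standardised; this table is the package's own
  documented default and is fully replaceable via a TSV. `X` maps to the
  per-property mean.

**Flank padding.** Window slots that fall off a chain end are filled with
a pad vector. The default is the per-attribute *training-set* mean of the
residue-level representation — neutral under a Gaussian likelihood, since
a mean-valued attribute contributes almost equally to both class
likelihoods — computed by the pipeline/CV layer from training chains only
and reused unchanged for held-out chains. A zero-padding mode exists for
comparison. When a chain is encoded standalone (no training context), the
chain's own mean is used.

**Normalisation.** Each attribute is min-max scaled into [0, 1] using the
training minimum and maximum only; constant attributes map to 0 and
out-of-range values at prediction time are clipped. Normalisation is
fitted per CV training fold, never on held-out chains — the leakage-safe
choice. (Min-max scaling is affine per attribute, so it does not change
Gaussian NB decisions on its own; it exists for parity with the standard
workflow and for numerical hygiene with heterogeneous property scales.)

## Classifier

Gaussian Naïve Bayes, written out in full rather than wrapped from a
library because the decision rule — not just the posterior — is the point:

- Priors are empirical class frequencies (binding-site data is heavily
  imbalanced, ~13.4% positive, and no re-weighting is applied), or can be
  imposed (e.g. 0.5/0.5) for threshold-free comparisons.
- Per attribute and class, the likelihood is `N(μ, σ²)` with μ, σ² the
  within-class sample mean and variance (population form, ddof = 0; at
  the sample sizes involved the distinction is immaterial).
- **Variance floor**: σ² is floored at `1e-9 ×` the attribute's training
  range, and absolutely at `1e-12`, so constant attributes cannot produce
  infinite ratios.
- The decision is `log-odds > log θ`, computed entirely in log space; at
  D = 100–240 attributes the raw product underflows doubles. Ties (ratio
  exactly θ) classify negative, matching the strict inequality; θ defaults
  to 1 and sweeping it traces the ROC curve.
- Models serialise to versioned JSON together with the pipeline state
  (pad vector, normaliser, encoder config), so a saved model reproduces
  scores bit-for-bit.

`FrequencyNB` is a deliberately tiny categorical variant whose
likelihoods are unsmoothed empirical frequency tables and whose joints
are computed as plain products. It exists so the decision rule can be
checked for *exact* agreement against brute-force enumeration of
`P(c)·∏P(xᵢ|c)` on small discrete problems; it is not part of the
prediction pipeline.

## Evaluation

From the confusion counts (TP, FP, TN, FN; N their sum):

- accuracy = 100·(TP+TN)/N, sensitivity = 100·TP/(TP+FN),
  specificity = 100·TN/(TN+FP) — sensitivity/specificity are reported as
  *undefined* (None), not 0, when their own denominator is 0;
- MCC = (TP·TN − FP·FN) / √((TP+FN)(TP+FP)(TN+FP)(TN+FN)), with MCC = 0
  when any denominator factor vanishes;
- net prediction, where mentioned in the field's tables, is
  (sensitivity + specificity)/2 and is derivable from the report.

ROC curves sweep thresholds over {+∞, each unique score descending, −∞}
with the same strict `>` rule as the classifier (thresholds on log-odds
correspond to log θ), deduplicate consecutive identical points, and report
the trapezoidal AUC. Every curve point is consistent with
`compute_metrics` at that threshold by construction and by test.

LOPO CV treats each chain as the unit: for every fold, pad vector,
normaliser and NB parameters are refitted on all chains but one. Pooled
(micro-averaged) counts over held-out residues are the headline numbers; a
per-chain table is kept alongside. A fold whose training set loses a class
is skipped with a warning rather than silently mis-fitted.

## Synthetic data

The generators define the package's test conditions:

- **Structures**: a pseudo-helical backbone (N/CA/C atoms, 3.8 Å CA
  spacing along x) with one het group. Each pocket residue's CA sits at
  *exactly* `pocket_distance` (default 3.0 Å) from one ligand atom;
  non-pocket residues are offset so their minimum ligand distance is
  ≥ `decoy_distance` (default 8.0 Å); a seeded z-jitter shared between
  each pocket residue and its ligand atom varies coordinates without
  disturbing either guarantee. Truth labels therefore follow from the
  construction alone, which is what makes the fixture a legitimate oracle
  for the contact code. Output is byte-identical for a given seed.
- **Profiles**: per-chain labels are Bernoulli draws at prevalence
  0.1343 — the binding-residue fraction of the curated 42-chain reference
  set (1431 of 10657 residues) — and profile rows are Gaussian with
  standard deviation `noise_sd` (default 1), with binding rows shifted by
  `effect_size` (default 2) on designated columns (default column 0).
  Matching the classifier's likelihood family is deliberate: with a single
  shifted column, `k = 0` and equal priors, the Bayes accuracy has the
  closed form `Φ(d/2σ)·100`, giving the calibration tests an analytic
  target (84.13% at the defaults). A Student-t(3) mode provides
  heavier-tailed noise for robustness checks.

What the synthetic data does *not* emulate: real evolutionary profiles
(PSSM columns are neither independent nor Gaussian in real data),
membrane-protein topology, correlated binding-site geometry along the
sequence, or inter-chain homology. Passing calibration tests therefore
demonstrates that the pipeline is correct and well-calibrated *under its
own model assumptions*; it does not certify accuracy figures on real
membrane-protein datasets, which depend on external structures and
sequence databases.

## Numerical and edge-case conventions

- All log-likelihood sums in float64; posterior odds are clamped at
  `exp(700)` to avoid overflow in the convenience `score` field.
- Empty ligand list → all-false labels (not an error); empty chain or
  empty sequence → error.
- PSSM parser accepts integer (native) and real-valued scores, requires
  contiguous 1-based positions, and names the offending line on malformed
  input. The writer round-trips both exactly.
- Determinism: every generator takes an explicit seed; model files are
  byte-identical across repeated runs on the same input.

## Problem sizes used in checks

Calibration runs use 20 chains × 500 residues (10 000 examples, 20
attributes at `k = 0`): large enough that the LOPO estimate sits well
inside the ±3-point band around the analytic Bayes accuracy (sampling
noise on the fitted means is ~0.03σ), small enough to keep the whole
verification suite in the seconds range. Contact-labeling equivalence is
checked on 50 generated structures of 6–50 residues with randomised
pockets and cutoffs; oracle-agreement checks use ≥200 discrete instances
and 1000 random label/prediction pairs.
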