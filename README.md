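# bindres

Sequence-based prediction of ligand-binding residues in alpha-helical
membrane proteins.

Membrane proteins mediate transport, signalling and energy conversion, and
most of what they do happens at ligand-binding sites — yet for the large
majority of membrane-protein sequences no structure is available to locate
those sites. `bindres` implements a classical sequence-only predictor of
per-residue ligand binding: each residue is represented by a sliding window
of per-residue feature vectors and classified by a Gaussian Naïve Bayes
model with a likelihood-ratio decision rule. It is aimed at structural
bioinformaticians who want a transparent, fully inspectable baseline
pipeline — from structure-derived ground truth to leave-one-protein-out
evaluation — rather than a black box.

## The model

Ground truth comes from structures: residue *i* is **binding** when any of
its atoms lies closer than a cutoff (default 4.5 Å, strict `<`) to any atom
of a ligand, where a ligand is any non-protein, non-water het group itself
in contact with the protein.

Each residue *t* is encoded as the window
`X = (x_{t-k}, …, x_t, …, x_{t+k})` with `s = 2k + 1` positions (default
`k = 2`, window size 5), where `x` is one of

- the residue's 20-component PSSM profile row (PSI-BLAST log-odds scores),
- its BLOSUM62 substitution-matrix row, or
- a vector of `P` physicochemical properties (48 by default).

Features are min-max normalised into [0, 1] with statistics learned from
the training chains only. The classifier assumes the `D = s·20` (or
`s·P`) attributes are conditionally independent given the class
`c ∈ {0, 1}` and models each attribute per class as a Gaussian. A residue
is called binding when the posterior-odds ratio exceeds a threshold θ:

```
P(c=1) ∏ᵢ P(xᵢ | c=1)
───────────────────────  >  θ        (θ = 1 by default; ties → negative)
P(c=0) ∏ᵢ P(xᵢ | c=0)
```

evaluated in log space. Evaluation is leave-one-protein-out: every chain
is held out in turn, and padding, normalisation and model parameters are
refitted from scratch on the remaining chains, so no residue-level
information leaks into the held-out fold. Reported metrics are pooled
accuracy, sensitivity, specificity, the Matthews correlation coefficient,
and ROC curves from the pooled log-odds scores.

Because real training data requires deposited structures and PSI-BLAST
runs against a sequence database, the package ships a synthetic-data
module that generates parseable PDB files with geometrically exact pockets
and class-conditional Gaussian profiles with known analytic Bayes accuracy
— every stage of the pipeline can be exercised and calibrated offline.

## Worked example

`examples/03_lopo_evaluation.py` simulates 10 chains × 300 residues at the
reference binding prevalence (13.43%), with binding residues shifted by 2
standard deviations on one profile column, and cross-validates the
PSSM-window-5 predictor:

```
chain      residues  sens%   spec%   acc%
sim000          300   59.5   96.1   91.0
sim001          300   42.3   97.8   93.0
...
sim009          300   34.8   97.2   87.7
pooled         3000   47.4   97.6   91.2   MCC 0.546
ROC AUC over pooled held-out scores: 0.916
```

Each row is one held-out chain scored by a model that never saw it; the
pooled row sums the per-fold confusion counts over all 3000 residues. The
other examples cover contact labelling from a structure
(`01_label_binding_residues.py`), training and annotating a new chain
(`02_train_and_predict.py`), and comparing the three encodings under
identical conditions (`04_compare_encoders.py`).

The same pipeline is available from the shell:

```bash
bindres label structure.pdb --out labels.tsv          # structure → labels
bindres train --manifest manifest.tsv --out model.json
bindres predict --model model.json --pssm chain.pssm  # per-residue odds
bindres evaluate --manifest manifest.tsv --out-dir results/
```

where the manifest is a TSV of `chain_id`, `pssm_path` (or `fasta_path`)
and `label_path` columns.

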