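"""Synthetic fixtures: toy structures with known pockets, synthetic profiles.

Real training data for this problem requires deposited membrane-protein
structures and PSI-BLAST runs against a sequence database.  This module
generates self-contained substitutes with known ground truth:

* :func:`simulate_structure` writes a parseable PDB text — a pseudo-helical
  poly-alanine backbone plus one het group — whose geometry guarantees that
  exactly the requested pocket residues have an atom at ``pocket_distance``
  from the ligand while every other residue stays at least
  ``decoy_distance`` away.  The returned label set is therefore exact by
  construction, with no distance scan involved.
* :func:`simulate_profiles` draws per-chain Gaussian PSSM-like profiles in
  which binding residues (drawn at a target prevalence) receive a mean
  shift on designated columns.  Because the columns match the classifier's
  Gaussian likelihood family, the two-class Bayes accuracy has the closed
  form Phi(d / 2*sigma) at equal priors, which calibration tests exploit.

The default prevalence, 0.1343, is the binding-residue fraction of the
curated 42-chain membrane-protein set this package targets (1431 binding
residues among 10657).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .pssm import AA_ORDER, PSSMProfile
from .structure import DEFAULT_CUTOFF, BindingLabelSet

# composition of the reference 42-chain dataset; source of the default prevalence
DATASET_TOTAL_RESIDUES = 10657
DATASET_BINDING_RESIDUES = 1431
DEFAULT_BINDING_FRACTION = DATASET_BINDING_RESIDUES / DATASET_TOTAL_RESIDUES  # 0.13428...

_CA_SPACING = 3.8  # consecutive C-alpha distance, Angstrom

__all__ = [
    "DATASET_TOTAL_RESIDUES",
    "DATASET_BINDING_RESIDUES",
    "DEFAULT_BINDING_FRACTION",
    "StructureSimSpec",
    "ProfileSimSpec",
    "simulate_structure",
    "simulate_profiles",
]


@dataclasses.dataclass(frozen=True)
class StructureSimSpec:
    """Geometry of a toy chain with an implanted ligand pocket."""

    chain_length: int
    pocket_positions: tuple[int, ...]
    pocket_distance: float = 3.0
    decoy_distance: float = 8.0
    seed: int = 0
    het_code: str = "LIG"
    chain_id: str = "A"

    def __post_init__(self):
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if not 0 < self.pocket_distance < self.decoy_distance:
            raise ValueError("need 0 < pocket_distance < decoy_distance")
        for p in self.pocket_positions:
            if not 0 <= p < self.chain_length:
                raise ValueError(f"pocket position {p} out of range")


def _pdb_line(record, serial, name, resname, chain, resseq, xyz, element):
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{resname:>4s} {chain:1s}"
        f"{resseq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
        f"          {element:>2s}"
    )


def simulate_structure(
    spec: StructureSimSpec, cutoff: float = DEFAULT_CUTOFF
) -> tuple[str, BindingLabelSet]:
    """Emit (PDB text, ground-truth labels) for a pocket-implanted toy chain.

    Backbone N/CA/C atoms run along x at 3.8 A CA spacing.  Each pocket
    residue's CA sits at exactly ``pocket_distance`` from one ligand atom
    directly above it (+y); non-pocket residues are offset in -y so their
    minimum ligand distance is at least ``decoy_distance``.  A shared
    seeded z-jitter between each pocket residue and its ligand atom keeps
    the pocket distances exact while varying the coordinates.

    ``cutoff`` fixes the truth: labels are True at the pocket positions iff
    ``pocket_distance < cutoff`` (a warning is issued when it is not, and
    when ``decoy_distance < cutoff`` would make the construction ambiguous).
    """
    if spec.pocket_distance >= cutoff and spec.pocket_positions:
        warnings.warn(
            "pocket_distance >= cutoff: pocket residues will not be labelled binding",
            stacklevel=2,
        )
    if spec.decoy_distance < cutoff:
        warnings.warn("decoy_distance < cutoff: non-pocket residues may contact", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    zs = rng.uniform(-0.5, 0.5, size=spec.chain_length).round(3)
    pocket = set(spec.pocket_positions)
    lines = []
    serial = 1
    for i in range(spec.chain_length):
        x = i * _CA_SPACING
        y = 0.0 if i in pocket else spec.pocket_distance - spec.decoy_distance
        z = float(zs[i])
        for name, dx, el in (("N", -1.2, "N"), ("CA", 0.0, "C"), ("C", 1.2, "C")):
            lines.append(
                _pdb_line("ATOM", serial, name, "ALA", spec.chain_id, i + 1, (x + dx, y, z), el)
            )
            serial += 1
    lines.append("TER")
    for j, i in enumerate(sorted(pocket), start=1):
        x = i * _CA_SPACING
        z = float(zs[i])
        lines.append(
            _pdb_line(
                "HETATM", serial, f"C{j}", spec.het_code, "L", 901,
                (x, spec.pocket_distance, z), "C",
            )
        )
        serial += 1
    lines.append("END")
    labels = np.zeros(spec.chain_length, dtype=bool)
    if spec.pocket_distance < cutoff:
        labels[list(pocket)] = True
    return "\n".join(lines) + "\n", BindingLabelSet(
        chain_id=spec.chain_id, labels=labels, cutoff=cutoff
    )


@dataclasses.dataclass(frozen=True)
class ProfileSimSpec:
    """Class-conditional Gaussian profile generator settings.

    Non-binding residue rows are N(0, noise_sd^2) in every column; binding
    rows are shifted by ``effect_size`` on ``shift_columns``.  With a single
    shifted column, equal priors and no window context the analytic Bayes
    accuracy is Phi(effect_size / (2 * noise_sd)) * 100.
    """

    n_chains: int = 20
    chain_length: int = 500
    binding_fraction: float = DEFAULT_BINDING_FRACTION
    effect_size: float = 2.0
    noise_sd: float = 1.0
    shift_columns: tuple[int, ...] = (0,)
    seed: int = 0
    heavy_tails: bool = False  # Student-t(3) noise instead of Gaussian

    def __post_init__(self):
        if not 0 < self.binding_fraction < 1:
            raise ValueError("binding_fraction must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_chains < 1 or self.chain_length < 1:
            raise ValueError("n_chains and chain_length must be >= 1")
        for c in self.shift_columns:
            if not 0 <= c < 20:
                raise ValueError("shift_columns must index the 20 profile columns")


def simulate_profiles(spec: ProfileSimSpec) -> list[tuple[str, PSSMProfile, np.ndarray]]:
    """Draw (chain_id, profile, labels) triples; reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    aa = np.array(list(AA_ORDER))
    for c in range(spec.n_chains):
        labels = rng.random(spec.chain_length) < spec.binding_fraction
        if spec.heavy_tails:
            noise = rng.standard_t(df=3, size=(spec.chain_length, 20))
        else:
            noise = rng.standard_normal((spec.chain_length, 20))
        scores = noise * spec.noise_sd
        scores[np.ix_(labels, list(spec.shift_columns))] += spec.effect_size
        sequence = "".join(rng.choice(aa, size=spec.chain_length))
        out.append((f"sim{c:03d}", PSSMProfile(sequence, scores), labels))
    return out
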