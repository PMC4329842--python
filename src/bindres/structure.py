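"""Protein-ligand contact extraction from PDB coordinate files.

Ground-truth labels for the classifier come from structures: a residue is a
ligand-binding residue when any of its atoms lies closer than a distance
cutoff (4.5 A by default, strict ``<``) to any atom of a bound ligand, where
a ligand is any non-protein, non-water heteroatom group that itself sits
within the cutoff of the protein.  Waters (HOH/DOD) are never ligands; ions
and crystallisation additives are kept.

Parsing is delegated to Bio.PDB; for alternate-location atoms only the
highest-occupancy conformer is kept, and by default only the first model of
multi-model files is read.  Contact queries use a k-d tree over ligand
atoms; tests hold this to exact agreement with an exhaustive all-pairs scan.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial import cKDTree

DEFAULT_CUTOFF = 4.5

WATER_CODES = {"HOH", "DOD", "WAT"}

# modified polymer residues kept in the chain (sequence code 'X') rather
# than treated as ligands
MODIFIED_POLYMER = {"MSE", "SEC", "PYL", "SEP", "TPO", "PTR"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

__all__ = [
    "DEFAULT_CUTOFF",
    "StructureParseError",
    "EmptyStructureError",
    "AtomSite",
    "ResidueSite",
    "LigandGroup",
    "Chain",
    "StructureRecord",
    "BindingLabelSet",
    "parse_structure",
    "identify_ligands",
    "label_binding_residues",
    "min_ligand_distances",
    "write_labels_tsv",
    "write_fasta",
]


class StructureParseError(ValueError):
    """Unreadable or malformed coordinate file."""


class EmptyStructureError(StructureParseError):
    """File contains no polymer chain."""


@dataclasses.dataclass
class AtomSite:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstrom
    occupancy: float
    altloc: str = " "

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.isfinite(self.coord).all():
            raise StructureParseError(f"bad coordinates for atom {self.name}")


@dataclasses.dataclass
class ResidueSite:
    chain_id: str
    seq_index: int  # 0-based, contiguous along the parsed chain
    residue_code: str  # one-letter code or 'X'
    atoms: list[AtomSite]
    author_number: int = 0  # deposited residue number, metadata only


@dataclasses.dataclass
class LigandGroup:
    het_code: str
    atoms: list[AtomSite]


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[ResidueSite]

    @property
    def sequence(self) -> str:
        return "".join(r.residue_code for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class StructureRecord:
    entry_id: str
    chains: list[Chain]
    ligands: list[LigandGroup]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")


@dataclasses.dataclass
class BindingLabelSet:
    chain_id: str
    labels: np.ndarray  # (chain length,) bool
    cutoff: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def _pick_conformers(residue) -> list[AtomSite]:
    """All atoms of a residue, keeping only the best altloc per atom name."""
    atoms = []
    for atom in residue:
        if atom.is_disordered():
            children = atom.disordered_get_list()
            best = max(children, key=lambda a: (a.get_occupancy() or 0.0, -ord(a.get_altloc())))
            atom = best
        occ = atom.get_occupancy()
        atoms.append(
            AtomSite(
                name=atom.get_name(),
                element=(atom.element or "").strip(),
                coord=atom.get_coord(),
                occupancy=1.0 if occ is None else float(occ),
                altloc=atom.get_altloc() or " ",
            )
        )
    return atoms


def parse_structure(path: str | Path, model_index: int = 0) -> StructureRecord:
    """Parse a PDB file into chains of ordered residues plus ligand groups.

    Waters are dropped; het groups become :class:`LigandGroup` entries; a
    handful of common modified residues (e.g. selenomethionine) stay in the
    polymer with sequence code ``'X'``.  Residues are re-indexed 0-based and
    contiguous; the deposited numbering is kept as metadata.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:
            raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path} contains no model")
    try:
        model = models[model_index]
    except IndexError:
        raise StructureParseError(
            f"{path} has {len(models)} model(s); model_index {model_index} out of range"
        ) from None

    chains: list[Chain] = []
    ligands: list[LigandGroup] = []
    for pdb_chain in model:
        residues: list[ResidueSite] = []
        for residue in pdb_chain:
            hetflag, resseq, _ = residue.get_id()
            resname = residue.get_resname().strip()
            is_het = hetflag.strip() != ""
            if resname in WATER_CODES:
                continue
            if is_het and resname not in MODIFIED_POLYMER and resname not in THREE_TO_ONE:
                ligands.append(LigandGroup(het_code=resname, atoms=_pick_conformers(residue)))
                continue
            code = THREE_TO_ONE.get(resname, "X")
            residues.append(
                ResidueSite(
                    chain_id=pdb_chain.id,
                    seq_index=len(residues),
                    residue_code=code,
                    atoms=_pick_conformers(residue),
                    author_number=resseq,
                )
            )
        if residues:
            chains.append(Chain(chain_id=pdb_chain.id, residues=residues))
    if not chains:
        raise EmptyStructureError(f"{path} contains no polymer chain")
    return StructureRecord(entry_id=path.stem, chains=chains, ligands=ligands)


def _atom_coords(atoms: list[AtomSite]) -> np.ndarray:
    return np.array([a.coord for a in atoms], dtype=float).reshape(-1, 3)


def _protein_coords(record: StructureRecord) -> np.ndarray:
    return np.vstack(
        [_atom_coords(r.atoms) for c in record.chains for r in c.residues]
    )


def identify_ligands(
    record: StructureRecord,
    cutoff: float = DEFAULT_CUTOFF,
    inclusive: bool = False,
) -> list[LigandGroup]:
    """Het groups with at least one atom within ``cutoff`` of any protein atom.

    ``inclusive`` switches the comparison from strict ``<`` to ``<=``.
    """
    if not record.ligands:
        return []
    tree = cKDTree(_protein_coords(record))
    kept = []
    for lig in record.ligands:
        d, _ = tree.query(_atom_coords(lig.atoms), k=1)
        dmin = float(np.min(d))
        if dmin <= cutoff if inclusive else dmin < cutoff:
            kept.append(lig)
    return kept


def min_ligand_distances(chain: Chain, ligands: list[LigandGroup]) -> np.ndarray:
    """Per-residue minimum atom-atom distance to any ligand atom (inf if none)."""
    n = len(chain.residues)
    if not ligands:
        return np.full(n, np.inf)
    lig_coords = np.vstack([_atom_coords(l.atoms) for l in ligands])
    tree = cKDTree(lig_coords)
    out = np.empty(n)
    for i, res in enumerate(chain.residues):
        d, _ = tree.query(_atom_coords(res.atoms), k=1)
        out[i] = float(np.min(d))
    return out


def label_binding_residues(
    chain: Chain,
    ligands: list[LigandGroup],
    cutoff: float = DEFAULT_CUTOFF,
    inclusive: bool = False,
) -> BindingLabelSet:
    """Label residue ``i`` True iff its minimum ligand distance is below cutoff.

    The default rule is strict (``< cutoff``): an atom pair at exactly the
    cutoff does not count as a contact.  An empty ligand list yields
    all-False labels.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not chain.residues:
        raise ValueError("chain has no residues")
    d = min_ligand_distances(chain, ligands)
    labels = (d <= cutoff) if inclusive else (d < cutoff)
    return BindingLabelSet(chain_id=chain.chain_id, labels=labels, cutoff=cutoff)


def write_labels_tsv(
    path: str | Path,
    chain: Chain,
    labels: BindingLabelSet,
    append: bool = False,
) -> None:
    """Write per-residue labels as TSV: chain_id, seq_index, residue_code, label."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("chain_id\tseq_index\tresidue_code\tlabel\n")
        for res, lab in zip(chain.residues, labels.labels):
            fh.write(f"{chain.chain_id}\t{res.seq_index}\t{res.residue_code}\t{int(lab)}\n")


def write_fasta(path: str | Path, record: StructureRecord) -> None:
    """Write every chain's extracted sequence as FASTA."""
    with open(path, "w") as fh:
        for chain in record.chains:
            fh.write(f">{record.entry_id}_{chain.chain_id}\n{chain.sequence}\n")
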