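import numpy as np
import pytest

import bindres as br


def pdb_atom_line(record, serial, name, resname, chain, resseq, xyz,
                  element, occupancy=1.0, altloc=" "):
    """One fixed-width PDB coordinate record."""
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{altloc}{resname:>3s} {chain:1s}"
        f"{resseq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{occupancy:>6.2f}{0.0:>6.2f}"
        f"          {element:>2s}"
    )


def make_pdb(path, protein_atoms, het_atoms=(), waters=()):
    """Write a minimal PDB file from (name, resname, resseq, xyz) tuples.

    protein_atoms become ATOM records on chain A; het_atoms HETATM records
    on chain L; waters HETATM HOH records.
    """
    lines = []
    serial = 1
    for name, resname, resseq, xyz in protein_atoms:
        lines.append(pdb_atom_line("ATOM", serial, name, resname, "A", resseq, xyz, name[0]))
        serial += 1
    lines.append("TER")
    for name, resname, resseq, xyz in het_atoms:
        lines.append(pdb_atom_line("HETATM", serial, name, resname, "L", resseq, xyz, name[0]))
        serial += 1
    for i, xyz in enumerate(waters, start=1):
        lines.append(pdb_atom_line("HETATM", serial, "O", "HOH", "W", 500 + i, xyz, "O"))
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


THREE_RESIDUE_PROTEIN = [
    ("N", "ALA", 1, (0.0, 0.0, 0.0)),
    ("CA", "ALA", 1, (1.5, 0.0, 0.0)),
    ("CA", "GLY", 2, (5.3, 0.0, 0.0)),
    ("CA", "SER", 3, (9.1, 0.0, 0.0)),
]


@pytest.fixture
def three_residue_pdb(tmp_path):
    """3-residue chain plus one HEM group 4.0 A from residue 2's CA."""
    return make_pdb(
        tmp_path / "toy.pdb",
        THREE_RESIDUE_PROTEIN,
        het_atoms=[("FE", "HEM", 901, (5.3, 4.0, 0.0))],
    )


def brute_force_labels(chain, ligands, cutoff=4.5, inclusive=False):
    """Exhaustive all-pairs distance scan: the contact-labeling oracle."""
    lig = np.array([a.coord for g in ligands for a in g.atoms], dtype=float)
    out = np.zeros(len(chain.residues), dtype=bool)
    if lig.size == 0:
        return out
    for i, res in enumerate(chain.residues):
        dmin = np.inf
        for atom in res.atoms:
            d = np.sqrt(((lig - atom.coord) ** 2).sum(axis=1)).min()
            dmin = min(dmin, d)
        out[i] = dmin <= cutoff if inclusive else dmin < cutoff
    return out


@pytest.fixture(scope="session")
def profile_chains():
    """Six simulated profile chains with a moderate class signal."""
    sims = br.simulate_profiles(
        br.ProfileSimSpec(n_chains=6, chain_length=150, effect_size=2.0, seed=11)
    )
    return [br.ChainData(cid, labels=lab, profile=prof) for cid, prof, lab in sims]
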