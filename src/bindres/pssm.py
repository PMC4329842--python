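"""Reading and writing PSI-BLAST ASCII position-specific scoring matrices.

A PSSM assigns each of the N positions of a query sequence a 20-component
log-odds score vector, one component per amino acid, summarising the
conservation observed during iterative database search.  This module parses
the standard ``-out_ascii_pssm`` dump (only the first 20-column block — the
log-odds scores — is used; the weighted-percentage block is ignored) and can
write files in the same layout, which is how synthetic profiles reach the
rest of the pipeline through the public file interface.

PSI-BLAST emits integer scores; the writer also accepts real-valued
profiles (emitted at full precision) so that simulated Gaussian profiles
survive a write/parse round trip exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

__all__ = ["AA_ORDER", "PSSMParseError", "PSSMProfile", "parse_pssm", "write_pssm", "read_fasta"]


class PSSMParseError(ValueError):
    """Malformed or inconsistent PSSM file."""


@dataclasses.dataclass
class PSSMProfile:
    """Per-residue 20-score profile for one chain.

    ``scores`` has one row per sequence position, columns in :data:`AA_ORDER`.
    """

    sequence: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise PSSMParseError(f"scores must be N x 20, got {self.scores.shape}")
        if self.scores.shape[0] != len(self.sequence):
            raise PSSMParseError(
                f"{self.scores.shape[0]} score rows for a "
                f"{len(self.sequence)}-residue sequence"
            )
        if not np.isfinite(self.scores).all():
            raise PSSMParseError("scores contain non-finite values")

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PSSMProfile)
            and self.sequence == other.sequence
            and self.scores.shape == other.scores.shape
            and bool(np.all(self.scores == other.scores))
        )


def _is_header(tokens: list[str]) -> bool:
    # column-label line: 40 (two blocks) or 20 single amino-acid letters
    return (
        len(tokens) in (20, 40)
        and all(len(t) == 1 and t.isalpha() for t in tokens)
        and "".join(tokens[:20]) == AA_ORDER
    )


_TERMINATORS = ("K ", "Lambda", "Standard", "PSI", "Gapped")


def parse_pssm(path: str | Path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM dump into a :class:`PSSMProfile`.

    Raises :class:`PSSMParseError` naming the offending line on malformed
    rows, and on gaps or duplicates in the position numbering.
    """
    lines = Path(path).read_text().splitlines()
    seq: list[str] = []
    rows: list[list[float]] = []
    in_data = False
    expected_index = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not in_data:
            if _is_header(tokens):
                in_data = True
            continue
        if not tokens or line.lstrip().startswith(_TERMINATORS):
            break
        if not tokens[0].isdigit():
            break  # footer (K/Lambda table) reached
        if len(tokens) < 22:
            raise PSSMParseError(f"line {lineno}: expected >= 22 fields, got {len(tokens)}")
        if int(tokens[0]) != expected_index:
            raise PSSMParseError(
                f"line {lineno}: position {tokens[0]}, expected {expected_index}"
            )
        aa = tokens[1]
        if len(aa) != 1 or not aa.isalpha():
            raise PSSMParseError(f"line {lineno}: bad residue code {aa!r}")
        try:
            row = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score ({exc})") from None
        seq.append(aa.upper())
        rows.append(row)
        expected_index += 1
    if not in_data:
        raise PSSMParseError("no PSSM column header found")
    if not rows:
        raise PSSMParseError("PSSM file contains no data rows")
    return PSSMProfile("".join(seq), np.array(rows))


def _fmt(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return repr(float(value))


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII PSSM layout.

    Integer scores are printed as integers (the native dialect); real-valued
    scores are printed at full precision and round-trip exactly through
    :func:`parse_pssm`.
    """
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapped real matches to pseudocounts",
        "           " + "  ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER),
    ]
    for i, (aa, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        scores = " ".join(_fmt(v) for v in row)
        pct = " ".join("0" for _ in range(20))
        out.append(f"{i:5d} {aa}   {scores}  {pct}  0.00 0.00")
    out.append("")
    Path(path).write_text("\n".join(out) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file (sequence-only workflows)."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
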