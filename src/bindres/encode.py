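"""Window feature encodings for per-residue classification.

A target residue is represented by the concatenated per-residue feature
vectors of a sliding window of ``s = 2k + 1`` sequence positions centred on
it (``k`` neighbours on each side; ``k = 2`` by default).  Three per-residue
representations are supported:

* physicochemical property vectors from a :class:`PropertyTable`
  (``D = s * P`` attributes),
* the residue's BLOSUM62 substitution-matrix row (``D = s * 20``),
* the residue's PSSM profile row (``D = s * 20``).

Window slots that fall off either end of the chain are filled with a pad
vector; by default this is the per-attribute mean of the residue-level
representation (neutral under a Gaussian likelihood), with a zero-padding
mode available.  Feature matrices can be min-max normalised into [0, 1]
with statistics learned from a training set only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .properties import AA_ORDER, default_scales
from .pssm import PSSMProfile

__all__ = [
    "AA_ORDER",
    "EncodingError",
    "PropertyTable",
    "WindowSpec",
    "EncodedDataset",
    "Normalizer",
    "window_stack",
    "property_base_matrix",
    "blosum_base_matrix",
    "pssm_base_matrix",
    "encode_properties",
    "encode_blosum",
    "encode_pssm",
    "fit_normalizer",
    "apply_normalizer",
    "blosum62_matrix",
]


class EncodingError(ValueError):
    """Raised for residues missing from a table or mismatched inputs."""


def _load_blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = mat[a, b]
    return out


_BLOSUM62 = _load_blosum62()


def blosum62_matrix() -> np.ndarray:
    """The 20x20 BLOSUM62 matrix in :data:`AA_ORDER` row/column order."""
    return _BLOSUM62.copy()


class PropertyTable:
    """Per-amino-acid property values: a 20 x P table indexed by residue.

    Parameters
    ----------
    values : pandas.DataFrame
        Index must contain the 20 standard one-letter codes; columns are
        property names.  All values must be finite.
    """

    def __init__(self, values: pd.DataFrame):
        missing = [aa for aa in AA_ORDER if aa not in values.index]
        if missing:
            raise EncodingError(f"property table missing amino acids: {missing}")
        if values.shape[1] < 1:
            raise EncodingError("property table needs at least one property")
        values = values.loc[list(AA_ORDER)].astype(float)
        if not np.isfinite(values.to_numpy()).all():
            raise EncodingError("property table contains non-finite values")
        self.values = values
        # unknown residue 'X' is represented by the per-property mean
        self._x_vector = values.to_numpy().mean(axis=0)

    @classmethod
    def default(cls) -> "PropertyTable":
        """The packaged 48-property table (28 scales + 20 identity flags)."""
        scales = default_scales()
        df = pd.DataFrame(scales, index=list(AA_ORDER))
        return cls(df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        """Read a table from TSV with amino acids as rows, properties as columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="aa")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_properties(self) -> int:
        return self.values.shape[1]

    def vector(self, aa: str) -> np.ndarray:
        if aa == "X":
            return self._x_vector.copy()
        try:
            return self.values.loc[aa].to_numpy()
        except KeyError:
            raise EncodingError(f"residue {aa!r} not in property table") from None


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding window of ``s = 2k + 1`` residues centred on the target."""

    k: int = 2

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("window half-width k must be >= 0")

    @property
    def s(self) -> int:
        return 2 * self.k + 1


@dataclasses.dataclass
class EncodedDataset:
    """Window feature matrix with labels and per-row chain provenance."""

    features: np.ndarray  # (M, D) float
    labels: np.ndarray  # (M,) bool
    provenance: list[tuple[str, int]]  # (chain_id, seq_index) per row
    attribute_names: list[str]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        m, d = self.features.shape
        if self.labels.shape != (m,):
            raise EncodingError("labels length does not match feature rows")
        if len(self.provenance) != m:
            raise EncodingError("provenance length does not match feature rows")
        if len(self.attribute_names) != d:
            raise EncodingError("attribute_names length does not match columns")

    @property
    def n_examples(self) -> int:
        return self.features.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.features.shape[1]

    @staticmethod
    def concatenate(parts: Sequence["EncodedDataset"]) -> "EncodedDataset":
        if not parts:
            raise EncodingError("cannot concatenate zero datasets")
        names = parts[0].attribute_names
        for p in parts[1:]:
            if p.attribute_names != names:
                raise EncodingError("attribute names differ between datasets")
        return EncodedDataset(
            features=np.vstack([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            provenance=[pv for p in parts for pv in p.provenance],
            attribute_names=list(names),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features, columns=self.attribute_names)
        df.insert(0, "chain_id", [c for c, _ in self.provenance])
        df.insert(1, "seq_index", [i for _, i in self.provenance])
        df.insert(2, "label", self.labels.astype(int))
        df.to_csv(path, sep="\t", index=False)


def window_stack(base: np.ndarray, k: int, pad: np.ndarray) -> np.ndarray:
    """Concatenate rows of ``base`` over a +/-k window around each position.

    ``base`` is the (N, P) residue-level representation; ``pad`` (length P)
    fills window slots that fall outside [0, N).  Returns (N, (2k+1)*P).
    """
    base = np.asarray(base, dtype=float)
    n, p = base.shape
    pad = np.asarray(pad, dtype=float)
    if pad.shape != (p,):
        raise EncodingError(f"pad vector must have length {p}, got {pad.shape}")
    padded = np.vstack([np.tile(pad, (k, 1)), base, np.tile(pad, (k, 1))]) if k else base
    cols = [padded[off : off + n] for off in range(2 * k + 1)]
    return np.hstack(cols)


def _resolve_pad(base: np.ndarray, pad: np.ndarray | None, pad_mode: str) -> np.ndarray:
    if pad is not None:
        return np.asarray(pad, dtype=float)
    if pad_mode == "mean":
        return base.mean(axis=0)
    if pad_mode == "zero":
        return np.zeros(base.shape[1])
    raise EncodingError(f"unknown pad_mode {pad_mode!r}")


def _window_names(base_names: Sequence[str], k: int) -> list[str]:
    return [f"{name}@{off:+d}" for off in range(-k, k + 1) for name in base_names]


def property_base_matrix(sequence: str, table: PropertyTable) -> np.ndarray:
    """(N, P) matrix of per-residue property vectors."""
    if not sequence:
        raise EncodingError("empty sequence")
    return np.vstack([table.vector(aa) for aa in sequence])


def blosum_base_matrix(sequence: str) -> np.ndarray:
    """(N, 20) matrix of BLOSUM62 rows; 'X' maps to the zero vector."""
    if not sequence:
        raise EncodingError("empty sequence")
    rows = np.empty((len(sequence), 20))
    for i, aa in enumerate(sequence):
        if aa == "X":
            rows[i] = 0.0
        else:
            j = AA_ORDER.find(aa)
            if j < 0:
                raise EncodingError(f"residue {aa!r} is not a standard amino acid")
            rows[i] = _BLOSUM62[j]
    return rows


def pssm_base_matrix(profile: PSSMProfile) -> np.ndarray:
    """(N, 20) matrix of profile scores (a copy)."""
    return np.array(profile.scores, dtype=float)


def _build(
    base: np.ndarray,
    labels: Sequence[bool],
    window: WindowSpec,
    base_names: Sequence[str],
    chain_id: str,
    pad: np.ndarray | None,
    pad_mode: str,
) -> EncodedDataset:
    labels = np.asarray(labels, dtype=bool)
    if labels.shape[0] != base.shape[0]:
        raise EncodingError(
            f"labels length {labels.shape[0]} does not match {base.shape[0]} residues"
        )
    pad_vec = _resolve_pad(base, pad, pad_mode)
    feats = window_stack(base, window.k, pad_vec)
    prov = [(chain_id, i) for i in range(base.shape[0])]
    return EncodedDataset(feats, labels, prov, _window_names(base_names, window.k))


def encode_properties(
    sequence: str,
    labels: Sequence[bool],
    table: PropertyTable | None = None,
    window: WindowSpec = WindowSpec(2),
    chain_id: str = "",
    pad: np.ndarray | None = None,
    pad_mode: str = "mean",
) -> EncodedDataset:
    """Encode a sequence with per-residue property vectors (D = s*P)."""
    table = table or PropertyTable.default()
    base = property_base_matrix(sequence, table)
    return _build(base, labels, window, table.names, chain_id, pad, pad_mode)


def encode_blosum(
    sequence: str,
    labels: Sequence[bool],
    window: WindowSpec = WindowSpec(2),
    chain_id: str = "",
    pad: np.ndarray | None = None,
    pad_mode: str = "mean",
) -> EncodedDataset:
    """Encode a sequence with BLOSUM62 rows (D = s*20)."""
    base = blosum_base_matrix(sequence)
    names = [f"blosum_{aa}" for aa in AA_ORDER]
    return _build(base, labels, window, names, chain_id, pad, pad_mode)


def encode_pssm(
    profile: PSSMProfile,
    labels: Sequence[bool],
    window: WindowSpec = WindowSpec(2),
    chain_id: str = "",
    pad: np.ndarray | None = None,
    pad_mode: str = "mean",
) -> EncodedDataset:
    """Encode a PSSM profile with its per-residue score rows (D = s*20)."""
    base = pssm_base_matrix(profile)
    names = [f"pssm_{aa}" for aa in AA_ORDER]
    return _build(base, labels, window, names, chain_id, pad, pad_mode)


class Normalizer:
    """Min-max scaling into [0, 1] with statistics from a training set only.

    Each attribute is mapped by ``(x - min) / (max - min)``; attributes that
    are constant in training map to 0, and out-of-range values (seen only at
    prediction time) are clipped into [0, 1].
    """

    def __init__(self):
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.min_ is not None

    def fit(self, features: np.ndarray) -> "Normalizer":
        features = np.asarray(features, dtype=float)
        if features.size == 0:
            raise EncodingError("cannot fit a normalizer on an empty matrix")
        self.min_ = features.min(axis=0)
        self.max_ = features.max(axis=0)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise EncodingError("normalizer has not been fitted")
        features = np.asarray(features, dtype=float)
        span = self.max_ - self.min_
        out = np.zeros_like(features)
        nz = span > 0
        out[:, nz] = (features[:, nz] - self.min_[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        if not self.fitted:
            raise EncodingError("normalizer has not been fitted")
        return {"min": self.min_.tolist(), "max": self.max_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        norm = cls()
        norm.min_ = np.asarray(d["min"], dtype=float)
        norm.max_ = np.asarray(d["max"], dtype=float)
        return norm


def fit_normalizer(train: EncodedDataset) -> Normalizer:
    """Learn per-attribute min/max from a training dataset."""
    return Normalizer().fit(train.features)


def apply_normalizer(state: Normalizer, data: EncodedDataset) -> EncodedDataset:
    """Return a copy of ``data`` with features scaled by the fitted state."""
    return EncodedDataset(
        state.transform(data.features),
        data.labels.copy(),
        list(data.provenance),
        list(data.attribute_names),
    )
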