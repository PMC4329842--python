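"""End-to-end predictor: encoding + normalisation + Naive Bayes in one object.

:class:`LigandBindingPredictor` owns everything that must be learned from
training chains and nothing else: the window pad vector (per-attribute mean
of the training residue representations), the min-max normaliser, and the
fitted Naive Bayes parameters.  Held-out chains are encoded with the
training pad vector and clipped into the training range, so no statistic
ever leaks from test to train.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import naive_bayes as nb
from .encode import (
    EncodedDataset,
    EncodingError,
    Normalizer,
    PropertyTable,
    WindowSpec,
    blosum_base_matrix,
    encode_blosum,
    encode_properties,
    encode_pssm,
    property_base_matrix,
    pssm_base_matrix,
)
from .pssm import PSSMProfile

ENCODERS = ("properties", "blosum62", "pssm")

__all__ = ["ENCODERS", "ChainData", "PredictorConfig", "LigandBindingPredictor"]


@dataclasses.dataclass
class ChainData:
    """One chain's input to training or prediction.

    ``profile`` is required for the PSSM encoder; the property and BLOSUM62
    encoders need only ``sequence`` (taken from the profile when absent).
    ``labels`` may be None for pure prediction inputs.
    """

    chain_id: str
    labels: np.ndarray | None = None
    sequence: str | None = None
    profile: PSSMProfile | None = None

    def __post_init__(self):
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
        if self.sequence is None and self.profile is not None:
            self.sequence = self.profile.sequence
        if self.sequence is None and self.profile is None:
            raise ValueError(f"chain {self.chain_id}: need a sequence or a profile")

    def __len__(self) -> int:
        return len(self.sequence if self.sequence is not None else self.profile)


@dataclasses.dataclass(frozen=True)
class PredictorConfig:
    encoder: str = "pssm"
    window_k: int = 2
    theta: float = 1.0
    pad_mode: str = "mean"  # "mean" (training-set mean) or "zero"
    normalize: bool = True

    def __post_init__(self):
        if self.encoder not in ENCODERS:
            raise ValueError(f"encoder must be one of {ENCODERS}")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.pad_mode not in ("mean", "zero"):
            raise ValueError("pad_mode must be 'mean' or 'zero'")


class LigandBindingPredictor:
    """Train on labelled chains; score per-residue binding odds on new chains."""

    def __init__(self, config: PredictorConfig | None = None, table: PropertyTable | None = None):
        self.config = config or PredictorConfig()
        self.table = table or (PropertyTable.default() if self.config.encoder == "properties" else None)
        self.pad_: np.ndarray | None = None
        self.normalizer_: Normalizer | None = None
        self.model_: nb.NBModel | None = None

    # -- encoding ----------------------------------------------------------

    def _base(self, chain: ChainData) -> np.ndarray:
        enc = self.config.encoder
        if enc == "pssm":
            if chain.profile is None:
                raise EncodingError(f"chain {chain.chain_id}: PSSM encoder needs a profile")
            return pssm_base_matrix(chain.profile)
        if enc == "blosum62":
            return blosum_base_matrix(chain.sequence)
        return property_base_matrix(chain.sequence, self.table)

    def _encode(self, chain: ChainData, pad: np.ndarray) -> EncodedDataset:
        window = WindowSpec(self.config.window_k)
        labels = (
            chain.labels
            if chain.labels is not None
            else np.zeros(len(chain), dtype=bool)
        )
        kw = dict(window=window, chain_id=chain.chain_id, pad=pad)
        if self.config.encoder == "pssm":
            return encode_pssm(chain.profile, labels, **kw)
        if self.config.encoder == "blosum62":
            return encode_blosum(chain.sequence, labels, **kw)
        return encode_properties(chain.sequence, labels, table=self.table, **kw)

    # -- training / scoring -------------------------------------------------

    def fit(
        self, chains: list[ChainData], priors: tuple[float, float] | None = None
    ) -> "LigandBindingPredictor":
        if not chains:
            raise ValueError("no training chains")
        for c in chains:
            if c.labels is None:
                raise ValueError(f"chain {c.chain_id} has no labels")
        bases = [self._base(c) for c in chains]
        if self.config.pad_mode == "mean":
            self.pad_ = np.vstack(bases).mean(axis=0)
        else:
            self.pad_ = np.zeros(bases[0].shape[1])
        train = EncodedDataset.concatenate([self._encode(c, self.pad_) for c in chains])
        if self.config.normalize:
            self.normalizer_ = Normalizer().fit(train.features)
            train = EncodedDataset(
                self.normalizer_.transform(train.features),
                train.labels,
                train.provenance,
                train.attribute_names,
            )
        else:
            self.normalizer_ = None
        self.model_ = nb.fit(train, theta=self.config.theta, priors=priors)
        return self

    @property
    def fitted(self) -> bool:
        return self.model_ is not None

    def score_chain(self, chain: ChainData) -> np.ndarray:
        """Per-residue log posterior-odds ratios."""
        if not self.fitted:
            raise ValueError("predictor has not been fitted")
        X = self._encode(chain, self.pad_).features
        if self.normalizer_ is not None:
            X = self.normalizer_.transform(X)
        scores, _ = nb.predict_batch(self.model_, X)
        return scores

    def predict_chain(
        self, chain: ChainData, theta: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(log_ratios, boolean labels) under the ratio-vs-theta rule."""
        theta = self.config.theta if theta is None else theta
        scores = self.score_chain(chain)
        return scores, scores > np.log(theta)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if not self.fitted:
            raise ValueError("cannot save an unfitted predictor")
        extras = {
            "config": dataclasses.asdict(self.config),
            "pad": self.pad_.tolist(),
        }
        if self.normalizer_ is not None:
            extras["normalizer"] = self.normalizer_.to_dict()
        if self.config.encoder == "properties":
            extras["property_table"] = {
                name: self.table.values[name].tolist() for name in self.table.names
            }
        nb.save_model(self.model_, path, extras=extras)

    @classmethod
    def load(cls, path: str | Path) -> "LigandBindingPredictor":
        model, extras = nb.load_model(path)
        config = PredictorConfig(**extras["config"])
        table = None
        if "property_table" in extras:
            import pandas as pd

            from .properties import AA_ORDER

            table = PropertyTable(
                pd.DataFrame(extras["property_table"], index=list(AA_ORDER))
            )
        predictor = cls(config, table=table)
        predictor.pad_ = np.asarray(extras["pad"], dtype=float)
        if "normalizer" in extras:
            predictor.normalizer_ = Normalizer.from_dict(extras["normalizer"])
        predictor.model_ = model
        return predictor
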