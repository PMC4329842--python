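"""Gaussian Naive Bayes with a likelihood-ratio decision rule.

The classifier assumes the D window attributes are conditionally independent
given the class c in {0, 1} (non-binding / binding) and models each
attribute within each class as a univariate Gaussian.  A residue is called
binding when the posterior-odds ratio

    P(c=1) prod_i P(x_i | c=1)
    --------------------------  >  theta
    P(c=0) prod_i P(x_i | c=0)

exceeds the decision threshold theta (1 by default; ties classify negative).
All products are evaluated as log sums: at D = 100-240 attributes the raw
likelihood product underflows double precision.

Class priors default to the empirical class frequencies — no re-weighting
despite the heavy class imbalance of binding-site data — but can be imposed
explicitly (e.g. equal priors for threshold-free comparisons).

:class:`FrequencyNB` is a small categorical variant whose likelihoods are
raw empirical frequency tables; it exists to support exact finite-sample
cross-checks of the decision rule against brute-force enumeration of the
joint distribution, and is not used in the prediction pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .encode import EncodedDataset

__all__ = [
    "FitError",
    "NBModel",
    "Prediction",
    "fit",
    "log_posterior_ratio",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
    "FrequencyNB",
]

_LOG_2PI = math.log(2.0 * math.pi)


class FitError(ValueError):
    """Training data unusable (single class, no attributes)."""


@dataclasses.dataclass
class NBModel:
    """Fitted parameters: priors, per-attribute per-class Gaussians, theta."""

    prior_0: float
    prior_1: float
    means: np.ndarray  # (2, D); row c holds mu_{i,c}
    variances: np.ndarray  # (2, D)
    theta: float = 1.0
    attribute_names: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.means.shape != self.variances.shape or self.means.shape[0] != 2:
            raise FitError("means/variances must both be (2, D)")
        if not (self.prior_0 > 0 and self.prior_1 > 0):
            raise FitError("priors must be positive")
        if abs(self.prior_0 + self.prior_1 - 1.0) > 1e-9:
            raise FitError("priors must sum to 1")
        if np.any(self.variances <= 0):
            raise FitError("variances must be positive")
        if self.theta <= 0:
            raise FitError("theta must be positive")

    @property
    def n_attributes(self) -> int:
        return self.means.shape[1]


@dataclasses.dataclass(frozen=True)
class Prediction:
    """One decision: log posterior-odds ratio, odds, and the binary call."""

    log_ratio: float
    label: bool
    score: float  # posterior odds, exp(log_ratio)


def fit(
    train: EncodedDataset,
    theta: float = 1.0,
    priors: tuple[float, float] | None = None,
    var_floor_rel: float = 1e-9,
    var_floor_abs: float = 1e-12,
) -> NBModel:
    """Estimate priors and per-attribute per-class Gaussian parameters.

    Variances are floored at ``var_floor_rel`` times the attribute's
    training range (and absolutely at ``var_floor_abs``) so that attributes
    constant within a class cannot produce infinite likelihood ratios.

    ``priors`` overrides the empirical class frequencies when given.
    """
    X, y = train.features, train.labels
    if X.shape[1] == 0:
        raise FitError("training data has zero attributes")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n0 == 0 or n1 == 0:
        raise FitError("training data must contain both classes")
    if priors is None:
        p0, p1 = n0 / (n0 + n1), n1 / (n0 + n1)
    else:
        p0, p1 = float(priors[0]), float(priors[1])
    rng_span = X.max(axis=0) - X.min(axis=0)
    floor = np.maximum(var_floor_rel * rng_span, var_floor_abs)
    means = np.vstack([X[~y].mean(axis=0), X[y].mean(axis=0)])
    variances = np.vstack([X[~y].var(axis=0), X[y].var(axis=0)])
    variances = np.maximum(variances, floor)
    return NBModel(
        prior_0=p0,
        prior_1=p1,
        means=means,
        variances=variances,
        theta=float(theta),
        attribute_names=list(train.attribute_names),
    )


def _log_gauss(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def log_posterior_ratio(model: NBModel, x: np.ndarray) -> float:
    """log P(c=1|x) - log P(c=0|x), computed entirely in log space."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_attributes,):
        raise ValueError(f"expected {model.n_attributes} attributes, got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("feature vector contains non-finite values")
    ll1 = _log_gauss(x, model.means[1], model.variances[1]).sum()
    ll0 = _log_gauss(x, model.means[0], model.variances[0]).sum()
    return float(math.log(model.prior_1) - math.log(model.prior_0) + ll1 - ll0)


def predict(model: NBModel, x: np.ndarray, theta: float | None = None) -> Prediction:
    """Apply the ratio-versus-theta rule to one feature vector.

    The inequality is strict: a ratio exactly equal to theta is classified
    negative.
    """
    theta = model.theta if theta is None else float(theta)
    if theta <= 0:
        raise ValueError("theta must be positive")
    lr = log_posterior_ratio(model, x)
    return Prediction(log_ratio=lr, label=lr > math.log(theta), score=math.exp(min(lr, 700.0)))


def predict_batch(
    model: NBModel, X: np.ndarray, theta: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised scoring: returns (log_ratios, labels) for an (M, D) matrix."""
    theta = model.theta if theta is None else float(theta)
    if theta <= 0:
        raise ValueError("theta must be positive")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_attributes:
        raise ValueError(f"expected (M, {model.n_attributes}) matrix, got {X.shape}")
    ll1 = _log_gauss(X, model.means[1], model.variances[1]).sum(axis=1)
    ll0 = _log_gauss(X, model.means[0], model.variances[0]).sum(axis=1)
    lr = math.log(model.prior_1) - math.log(model.prior_0) + ll1 - ll0
    return lr, lr > math.log(theta)


_FORMAT_VERSION = 1


def save_model(model: NBModel, path: str | Path, extras: dict | None = None) -> None:
    """Serialise a model (plus optional pipeline state) to versioned JSON."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "model": {
            "prior_0": model.prior_0,
            "prior_1": model.prior_1,
            "means": model.means.tolist(),
            "variances": model.variances.tolist(),
            "theta": model.theta,
            "attribute_names": model.attribute_names,
        },
    }
    if extras:
        doc["extras"] = extras
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> tuple[NBModel, dict]:
    """Load a model saved by :func:`save_model`; returns (model, extras)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')}")
    m = doc["model"]
    model = NBModel(
        prior_0=m["prior_0"],
        prior_1=m["prior_1"],
        means=np.array(m["means"]),
        variances=np.array(m["variances"]),
        theta=m["theta"],
        attribute_names=list(m["attribute_names"]),
    )
    return model, doc.get("extras", {})


class FrequencyNB:
    """Categorical Naive Bayes with raw empirical frequency likelihoods.

    Joint scores are computed as plain probability products (no logs, no
    smoothing) so that decisions agree bit-for-bit with exhaustive
    enumeration of P(c) * prod_i P(x_i | c) from the training counts.
    Intended for exact cross-checking on tiny discrete problems, not for
    prediction at scale.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=int)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise FitError("X must be (M, D) aligned with y")
        if y.all() or not y.any():
            raise FitError("training data must contain both classes")
        self.n_attributes = X.shape[1]
        n = len(y)
        self.priors = (int((~y).sum()) / n, int(y.sum()) / n)
        # tables[c][i] maps value -> empirical P(value | class c)
        self.tables: tuple[list[dict[int, float]], list[dict[int, float]]] = ([], [])
        for c, mask in enumerate((~y, y)):
            rows = X[mask]
            for i in range(self.n_attributes):
                vals, counts = np.unique(rows[:, i], return_counts=True)
                self.tables[c].append(
                    {int(v): int(k) / len(rows) for v, k in zip(vals, counts)}
                )

    def joint(self, x: np.ndarray, c: int) -> float:
        """P(c) * prod_i P(x_i | c) from the empirical tables."""
        p = self.priors[c]
        for i, v in enumerate(np.asarray(x, dtype=int)):
            p = p * self.tables[c][i].get(int(v), 0.0)
        return float(p)

    def predict(self, x: np.ndarray, theta: float = 1.0) -> bool:
        """True iff joint(x, 1) > theta * joint(x, 0)."""
        return bool(self.joint(x, 1) > theta * self.joint(x, 0))
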