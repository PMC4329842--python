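"""Confusion-matrix metrics, ROC curves, and leave-one-protein-out CV.

Headline numbers are pooled (micro-averaged) over all residues of all
held-out chains; a per-chain breakdown is kept alongside.  Folds are
defined by chain — every residue of the held-out chain is scored by a model
that never saw any residue of that chain, including the normalisation and
padding statistics.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import numpy as np

from .naive_bayes import FitError
from .pipeline import ChainData, LigandBindingPredictor, PredictorConfig
from .encode import PropertyTable

__all__ = [
    "EvaluationError",
    "MetricsReport",
    "ROCCurve",
    "CVResult",
    "compute_metrics",
    "roc_curve",
    "lopo_cv",
    "write_cv_tsv",
]


class EvaluationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived percentage metrics.

    ``sensitivity``/``specificity`` are None (undefined) when their own
    denominator is zero; MCC uses the convention MCC = 0 when any factor of
    its denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.n == 0:
            raise EvaluationError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return None if denom == 0 else 100.0 * self.tp / denom

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return None if denom == 0 else 100.0 * self.tn / denom

    @property
    def mcc(self) -> float:
        factors = [
            self.tp + self.fn,
            self.tp + self.fp,
            self.tn + self.fp,
            self.tn + self.fn,
        ]
        if any(f == 0 for f in factors):
            return 0.0
        num = self.tp * self.tn - self.fp * self.fn
        return num / math.sqrt(math.prod(factors))

    def __add__(self, other: "MetricsReport") -> "MetricsReport":
        return MetricsReport(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def compute_metrics(labels, predictions) -> MetricsReport:
    """Confusion counts from aligned boolean truth/prediction vectors."""
    labels = np.asarray(labels, dtype=bool)
    predictions = np.asarray(predictions, dtype=bool)
    if labels.shape != predictions.shape or labels.ndim != 1 or labels.size == 0:
        raise EvaluationError("labels and predictions must be equal-length nonempty vectors")
    return MetricsReport(
        tp=int((labels & predictions).sum()),
        fp=int((~labels & predictions).sum()),
        tn=int((~labels & ~predictions).sum()),
        fn=int((labels & ~predictions).sum()),
    )


@dataclasses.dataclass
class ROCCurve:
    """Operating points of the strict score > threshold rule.

    ``thresholds`` runs from +inf down to -inf; consecutive duplicate
    (fpr, tpr) points are dropped.  The curve therefore starts at (0, 0)
    and ends at (1, 1); ``auc`` is the trapezoidal area.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for t, f, s in zip(self.thresholds, self.fpr, self.tpr):
                fh.write(f"{t}\t{f}\t{s}\n")


def roc_curve(scores, labels) -> ROCCurve:
    """ROC over thresholds = {+inf, each unique score (descending), -inf}.

    A sample is predicted positive at threshold t iff its score is strictly
    greater than t, mirroring the classifier's ratio-vs-theta rule (for
    log-odds scores, t corresponds to log theta).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length vectors")
    pos = int(labels.sum())
    neg = int((~labels).sum())
    if pos == 0 or neg == 0:
        raise EvaluationError("ROC requires both classes")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    cum_tp = np.cumsum(l_sorted)
    cum_fp = np.cumsum(~l_sorted)
    # block starts of each unique (descending) score value
    starts = np.flatnonzero(np.r_[True, s_sorted[1:] != s_sorted[:-1]])
    uniq = s_sorted[starts]
    # at threshold = uniq[j], positives are the `starts[j]` strictly greater scores
    tp_counts = np.r_[0, np.where(starts > 0, cum_tp[starts - 1], 0), pos]
    fp_counts = np.r_[0, np.where(starts > 0, cum_fp[starts - 1], 0), neg]
    thresholds = np.r_[np.inf, uniq, -np.inf]
    tpr = tp_counts / pos
    fpr = fp_counts / neg
    keep = np.r_[True, (np.diff(tpr) != 0) | (np.diff(fpr) != 0)]
    thresholds, fpr, tpr = thresholds[keep], fpr[keep], tpr[keep]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


@dataclasses.dataclass
class CVResult:
    """Leave-one-protein-out outcome: per-chain and pooled reports."""

    per_chain: list[tuple[str, MetricsReport]]
    pooled: MetricsReport
    scores: np.ndarray  # held-out log-odds scores, pooled over folds
    score_labels: np.ndarray  # true labels aligned with `scores`
    skipped: list[str] = dataclasses.field(default_factory=list)

    def roc(self) -> ROCCurve:
        return roc_curve(self.scores, self.score_labels)


def lopo_cv(
    chains: list[ChainData],
    config: PredictorConfig | None = None,
    table: PropertyTable | None = None,
    priors: tuple[float, float] | None = None,
) -> CVResult:
    """Leave-one-protein-out cross-validation over labelled chains.

    For every fold the pad vector, the normaliser, and the Naive Bayes
    parameters are fitted on all chains but one; the held-out chain is then
    scored and thresholded at the configured theta.  A fold whose training
    set loses a class is skipped with a warning.  Pooled counts are the sum
    of the per-chain counts by construction.
    """
    if len(chains) < 2:
        raise EvaluationError("leave-one-protein-out needs at least 2 chains")
    for c in chains:
        if c.labels is None:
            raise EvaluationError(f"chain {c.chain_id} has no labels")
    config = config or PredictorConfig()
    per_chain: list[tuple[str, MetricsReport]] = []
    skipped: list[str] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    counts = np.zeros(4, dtype=int)  # tp, fp, tn, fn
    for i, held in enumerate(chains):
        train = chains[:i] + chains[i + 1 :]
        predictor = LigandBindingPredictor(config, table=table)
        try:
            predictor.fit(train, priors=priors)
        except FitError as exc:
            warnings.warn(f"fold {held.chain_id}: {exc}; fold skipped", stacklevel=2)
            skipped.append(held.chain_id)
            continue
        scores, preds = predictor.predict_chain(held)
        report = compute_metrics(held.labels, preds)
        per_chain.append((held.chain_id, report))
        counts += np.array([report.tp, report.fp, report.tn, report.fn])
        all_scores.append(scores)
        all_labels.append(held.labels)
    if not per_chain:
        raise EvaluationError("every fold was skipped")
    pooled = MetricsReport(*counts.tolist())
    return CVResult(
        per_chain=per_chain,
        pooled=pooled,
        scores=np.concatenate(all_scores),
        score_labels=np.concatenate(all_labels),
        skipped=skipped,
    )


def _fmt_pct(v: float | None) -> str:
    return "NA" if v is None else f"{v:.2f}"


def write_cv_tsv(result: CVResult, path: str | Path) -> None:
    """Per-chain table (id, residues, sensitivity, specificity, accuracy)
    followed by the pooled summary row."""
    with open(path, "w") as fh:
        fh.write("chain_id\tresidues\tsensitivity\tspecificity\taccuracy\tmcc\n")
        for chain_id, rep in result.per_chain:
            fh.write(
                f"{chain_id}\t{rep.n}\t{_fmt_pct(rep.sensitivity)}\t"
                f"{_fmt_pct(rep.specificity)}\t{rep.accuracy:.2f}\t{rep.mcc:.4f}\n"
            )
        rep = result.pooled
        fh.write(
            f"POOLED\t{rep.n}\t{_fmt_pct(rep.sensitivity)}\t"
            f"{_fmt_pct(rep.specificity)}\t{rep.accuracy:.2f}\t{rep.mcc:.4f}\n"
        )
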