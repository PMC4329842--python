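"""Metrics, ROC curves, and leave-one-protein-out cross-validation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bindres as br
from bindres.evaluate import (
    EvaluationError,
    MetricsReport,
    compute_metrics,
    lopo_cv,
    roc_curve,
    write_cv_tsv,
)
from bindres.pipeline import ChainData, LigandBindingPredictor, PredictorConfig
from bindres.pssm import PSSMProfile


def counting_oracle(labels, predictions):
    """Independent per-element enumeration of the confusion counts."""
    tp = fp = tn = fn = 0
    for lab, pred in zip(labels, predictions):
        if lab and pred:
            tp += 1
        elif not lab and pred:
            fp += 1
        elif not lab and not pred:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


class TestMetrics:
    def test_perfect_predictions(self):
        labels = np.array([1, 0, 1, 0, 1], dtype=bool)
        rep = compute_metrics(labels, labels)
        assert rep.accuracy == 100.0
        assert rep.mcc == 1.0

    def test_inverted_predictions(self):
        labels = np.array([1, 0, 1, 0], dtype=bool)
        rep = compute_metrics(labels, ~labels)
        assert rep.accuracy == 0.0
        assert rep.mcc == -1.0

    def test_hand_computed_counts(self):
        # TP=3 FP=1 TN=5 FN=1
        rep = MetricsReport(tp=3, fp=1, tn=5, fn=1)
        assert rep.accuracy == pytest.approx(80.0)
        assert rep.sensitivity == pytest.approx(75.0)
        assert rep.specificity == pytest.approx(83.3333, abs=1e-3)
        # (3*5 - 1*1) / sqrt(4 * 4 * 6 * 6) = 14/24
        assert rep.mcc == pytest.approx(14 / 24)

    def test_undefined_sensitivity_reported_as_none_not_zero(self):
        rep = compute_metrics(np.zeros(4, dtype=bool), np.array([1, 0, 0, 0], dtype=bool))
        assert rep.sensitivity is None
        assert rep.specificity == pytest.approx(75.0)
        assert rep.mcc == 0.0  # zero-denominator convention

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics(np.zeros(3, dtype=bool), np.zeros(4, dtype=bool))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 60), st.integers(0, 2**31 - 1))
    def test_matches_counting_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.random(n) < 0.4
        preds = rng.random(n) < 0.5
        rep = compute_metrics(labels, preds)
        tp, fp, tn, fn = counting_oracle(labels, preds)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)
        assert rep.accuracy == pytest.approx(100.0 * (tp + tn) / n)
        assert -1.0 <= rep.mcc <= 1.0
        assert 0.0 <= rep.accuracy <= 100.0


class TestROC:
    def test_perfectly_separating_scores_have_auc_one(self):
        labels = np.array([0, 0, 0, 1, 1], dtype=bool)
        scores = np.array([-2.0, -1.5, -0.3, 1.0, 2.0])
        assert roc_curve(scores, labels).auc == pytest.approx(1.0)

    def test_two_example_hand_enumeration(self):
        curve = roc_curve(np.array([1.0, 0.0]), np.array([True, False]))
        np.testing.assert_allclose(curve.fpr, [0.0, 0.0, 1.0])
        np.testing.assert_allclose(curve.tpr, [0.0, 1.0, 1.0])

    def test_curve_bounds_and_monotonicity(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        labels[:2] = [True, False]
        curve = roc_curve(scores, labels)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.thresholds) < 0)

    def test_points_consistent_with_compute_metrics(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.35
        labels[:2] = [True, False]
        curve = roc_curve(scores, labels)
        for t, fpr, tpr in zip(curve.thresholds, curve.fpr, curve.tpr):
            preds = scores > t
            if not preds.any() and fpr == 0 and tpr == 0:
                continue
            rep = compute_metrics(labels, preds)
            assert tpr == pytest.approx(rep.tp / (rep.tp + rep.fn))
            assert fpr == pytest.approx(rep.fp / (rep.fp + rep.tn))

    def test_matches_sklearn_auc(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(17)
        scores = rng.normal(size=500)
        labels = rng.random(500) < 0.2
        labels[:2] = [True, False]
        scores[labels] += 0.7
        ours = roc_curve(scores, labels).auc
        assert ours == pytest.approx(metrics.roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve(np.array([0.1, 0.2]), np.array([True, True]))


def _chain(cid, scores, labels, sequence=None):
    n = len(labels)
    seq = sequence or "A" * n
    return ChainData(cid, labels=np.asarray(labels, dtype=bool),
                     profile=PSSMProfile(seq, np.asarray(scores, dtype=float)))


class TestLOPO:
    def test_two_identical_chains_give_identical_reports(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(40, 20))
        labels = rng.random(40) < 0.3
        labels[:2] = [True, False]
        scores[labels, 0] += 2.0
        chains = [_chain("a", scores, labels), _chain("b", scores.copy(), labels.copy())]
        res = lopo_cv(chains, PredictorConfig(encoder="pssm", window_k=0))
        (ca, ra), (cb, rb) = res.per_chain
        assert {ca, cb} == {"a", "b"}
        assert (ra.tp, ra.fp, ra.tn, ra.fn) == (rb.tp, rb.fp, rb.tn, rb.fn)

    def test_pooled_counts_equal_sum_of_folds(self, profile_chains):
        res = lopo_cv(profile_chains, PredictorConfig(encoder="pssm", window_k=1))
        total = np.zeros(4, dtype=int)
        for _, rep in res.per_chain:
            total += [rep.tp, rep.fp, rep.tn, rep.fn]
        assert (res.pooled.tp, res.pooled.fp, res.pooled.tn, res.pooled.fn) == tuple(total)
        assert res.pooled.n == sum(len(c) for c in profile_chains)

    def test_fold_with_single_class_training_is_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        mixed = _chain("mixed", rng.normal(size=(30, 20)),
                       [True] * 10 + [False] * 20)
        neg1 = _chain("neg1", rng.normal(size=(30, 20)), [False] * 30)
        neg2 = _chain("neg2", rng.normal(size=(30, 20)), [False] * 30)
        with pytest.warns(UserWarning, match="skipped"):
            res = lopo_cv([mixed, neg1, neg2], PredictorConfig(encoder="pssm", window_k=0))
        assert res.skipped == ["mixed"]
        assert {cid for cid, _ in res.per_chain} == {"neg1", "neg2"}

    def test_held_out_scores_do_not_depend_on_held_out_labels(self, profile_chains):
        """No leakage: a chain's own labels never reach its fold's model."""
        res1 = lopo_cv(profile_chains, PredictorConfig(encoder="pssm", window_k=0))
        target = profile_chains[0]
        # fit on the other chains, score the target under two different truths
        predictor = LigandBindingPredictor(PredictorConfig(encoder="pssm", window_k=0))
        predictor.fit(profile_chains[1:])
        s1 = predictor.score_chain(target)
        flipped = ChainData(target.chain_id, labels=~target.labels, profile=target.profile)
        s2 = predictor.score_chain(flipped)
        np.testing.assert_array_equal(s1, s2)
        # and lopo_cv's fold used exactly this training set
        np.testing.assert_allclose(res1.scores[: len(target)], s1)

    def test_fewer_than_two_chains_rejected(self, profile_chains):
        with pytest.raises(EvaluationError):
            lopo_cv(profile_chains[:1])

    def test_cv_tsv_has_per_chain_rows_and_pooled_summary(self, tmp_path, profile_chains):
        res = lopo_cv(profile_chains, PredictorConfig(encoder="pssm", window_k=0))
        path = tmp_path / "cv.tsv"
        write_cv_tsv(res, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("chain_id\t")
        assert len(lines) == len(profile_chains) + 2
        assert lines[-1].startswith("POOLED")


def test_signal_beats_no_signal_in_lopo():
    cfg = PredictorConfig(encoder="pssm", window_k=0)
    strong = br.simulate_profiles(br.ProfileSimSpec(n_chains=6, chain_length=150,
                                                    effect_size=3.0, seed=5))
    null = br.simulate_profiles(br.ProfileSimSpec(n_chains=6, chain_length=150,
                                                  effect_size=0.0, seed=5))
    res_s = lopo_cv([ChainData(c, labels=l, profile=p) for c, p, l in strong], cfg)
    res_0 = lopo_cv([ChainData(c, labels=l, profile=p) for c, p, l in null], cfg)
    assert res_s.pooled.mcc > 0.35
    assert res_s.roc().auc > 0.85
    assert abs(res_0.pooled.mcc) < 0.15
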