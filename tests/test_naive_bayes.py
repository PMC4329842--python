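"""Gaussian Naive Bayes: fitting, log-ratio scoring, decision rule."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from bindres.encode import EncodedDataset
from bindres.naive_bayes import (
    FitError,
    FrequencyNB,
    NBModel,
    fit,
    load_model,
    log_posterior_ratio,
    predict,
    predict_batch,
    save_model,
)


def dataset(X, y):
    X = np.asarray(X, dtype=float)
    names = [f"a{i}" for i in range(X.shape[1])]
    return EncodedDataset(X, np.asarray(y, dtype=bool), [("c", i) for i in range(len(X))], names)


def two_gaussian_model(m0, m1, var=1.0, p1=0.5, theta=1.0):
    return NBModel(
        prior_0=1 - p1, prior_1=p1,
        means=np.array([[m0], [m1]], dtype=float),
        variances=np.array([[var], [var]], dtype=float),
        theta=theta, attribute_names=["a0"],
    )


class TestFit:
    def test_two_point_estimates(self):
        ds = dataset([[0.0], [0.0], [1.0], [1.0]], [0, 0, 1, 1])
        model = fit(ds)
        assert model.prior_0 == model.prior_1 == 0.5
        np.testing.assert_allclose(model.means, [[0.0], [1.0]])

    def test_balanced_priors_contribute_zero_to_log_ratio(self):
        ds = dataset([[0.0], [1.0], [0.0], [1.0]], [0, 0, 1, 1])
        model = fit(ds)
        # identical class-conditional parameters and equal priors
        assert log_posterior_ratio(model, np.array([0.37])) == pytest.approx(0.0, abs=1e-12)

    def test_empirical_priors_match_class_frequencies(self):
        rng = np.random.default_rng(0)
        y = rng.random(10000) < 0.1343
        y[0], y[1] = True, False
        X = rng.normal(size=(10000, 2))
        model = fit(dataset(X, y))
        assert model.prior_1 == pytest.approx(y.mean())

    def test_imposed_priors_override_frequencies(self):
        ds = dataset([[0.0], [0.0], [0.0], [1.0]], [0, 0, 0, 1])
        model = fit(ds, priors=(0.8657, 0.1343))
        assert model.prior_1 == pytest.approx(0.1343)

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            fit(dataset([[0.0], [1.0]], [0, 0]))

    def test_zero_attributes_rejected(self):
        with pytest.raises(FitError):
            fit(dataset(np.zeros((4, 0)), [0, 0, 1, 1]))

    def test_constant_attribute_gets_floored_variance(self):
        ds = dataset([[5.0, 0.0], [5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], [0, 0, 1, 1])
        model = fit(ds)
        assert np.all(model.variances > 0)
        # a constant attribute must not blow up the ratio
        assert np.isfinite(log_posterior_ratio(model, np.array([5.0, 1.5])))


class TestLogRatio:
    def test_symmetric_model_scores_zero_everywhere(self):
        model = two_gaussian_model(2.0, 2.0, var=3.0)
        for x in (-5.0, 0.0, 2.0, 11.0):
            assert log_posterior_ratio(model, np.array([x])) == pytest.approx(0.0, abs=1e-12)

    def test_decision_boundary_at_midpoint_of_means(self):
        model = two_gaussian_model(m0=-1.0, m1=3.0)
        root = brentq(lambda x: log_posterior_ratio(model, np.array([x])), -1.0, 3.0,
                      xtol=1e-12)
        assert abs(root - 1.0) < 1e-9

    def test_matches_direct_product_evaluation(self):
        rng = np.random.default_rng(4)
        means = rng.normal(size=(2, 3))
        variances = rng.uniform(0.5, 2.0, size=(2, 3))
        model = NBModel(prior_0=0.7, prior_1=0.3, means=means, variances=variances,
                        attribute_names=["a", "b", "c"])
        for _ in range(25):
            x = rng.normal(size=3)
            direct = (0.3 * np.prod(norm.pdf(x, means[1], np.sqrt(variances[1]))))
            direct /= 0.7 * np.prod(norm.pdf(x, means[0], np.sqrt(variances[0])))
            assert log_posterior_ratio(model, x) == pytest.approx(np.log(direct), abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        model = two_gaussian_model(0.0, 1.0)
        with pytest.raises(ValueError):
            log_posterior_ratio(model, np.array([0.0, 1.0]))


class TestDecisionRule:
    def test_tie_at_theta_classifies_negative(self):
        model = two_gaussian_model(2.0, 2.0)  # ratio exactly 1 everywhere
        pred = predict(model, np.array([0.0]), theta=1.0)
        assert pred.log_ratio == pytest.approx(0.0, abs=1e-12)
        assert pred.label is False

    def test_theta_limits(self):
        model = two_gaussian_model(-1.0, 1.0)
        xs = np.linspace(-4, 4, 9).reshape(-1, 1)
        _, all_pos = predict_batch(model, xs, theta=1e-300)
        _, all_neg = predict_batch(model, xs, theta=1e300)
        assert all_pos.all()
        assert not all_neg.any()

    def test_positive_set_shrinks_as_theta_grows(self):
        rng = np.random.default_rng(9)
        model = two_gaussian_model(-0.5, 0.5)
        X = rng.normal(size=(200, 1))
        prev = None
        for theta in (0.1, 0.5, 1.0, 2.0, 10.0):
            _, labels = predict_batch(model, X, theta=theta)
            if prev is not None:
                assert np.all(labels <= prev)
            prev = labels

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(2)
        ds = dataset(rng.normal(size=(60, 4)), rng.random(60) < 0.3)
        model = fit(ds)
        scores, labels = predict_batch(model, ds.features)
        for i in range(0, 60, 7):
            p = predict(model, ds.features[i])
            assert p.log_ratio == pytest.approx(scores[i], rel=1e-12)
            assert p.label == labels[i]


def test_shifting_one_attribute_everywhere_leaves_predictions_unchanged():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(300, 5))
    y = rng.random(300) < 0.3
    y[:2] = [True, False]
    Xs = X.copy()
    Xs[:, 2] += 137.0  # same constant in both classes, train and test
    _, base = predict_batch(fit(dataset(X, y)), X)
    _, shifted = predict_batch(fit(dataset(Xs, y)), Xs)
    np.testing.assert_array_equal(base, shifted)


def test_parameter_recovery_on_generative_draws():
    rng = np.random.default_rng(12)
    n = 10_000
    y = rng.random(n) < 0.3
    mu = np.array([[0.0, -1.0], [2.0, 0.5]])
    sd = np.array([[1.0, 0.5], [1.5, 1.0]])
    X = np.where(y[:, None], rng.normal(mu[1], sd[1], (n, 2)), rng.normal(mu[0], sd[0], (n, 2)))
    model = fit(dataset(X, y))
    assert model.prior_1 == pytest.approx(0.3, abs=0.02)
    np.testing.assert_allclose(model.means, mu, atol=0.06)
    np.testing.assert_allclose(np.sqrt(model.variances), sd, rtol=0.06)


def test_agrees_with_sklearn_gaussian_nb():
    """Independent reference implementation on the same Gaussian model."""
    sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
    rng = np.random.default_rng(21)
    X = rng.normal(size=(400, 6))
    y = rng.random(400) < 0.25
    y[:2] = [True, False]
    X[y] += 0.8
    model = fit(dataset(X, y), var_floor_rel=0.0, var_floor_abs=1e-300)
    ref = sklearn_nb.GaussianNB(var_smoothing=1e-300).fit(X, y)
    ours, _ = predict_batch(model, X)
    theirs = ref.predict_log_proba(X)
    np.testing.assert_allclose(ours, theirs[:, 1] - theirs[:, 0], atol=1e-8)


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    model = fit(dataset(rng.normal(size=(50, 3)), rng.random(50) < 0.4), theta=2.5)
    path = tmp_path / "model.json"
    save_model(model, path, extras={"note": "fixture"})
    again, extras = load_model(path)
    assert extras == {"note": "fixture"}
    assert again.theta == model.theta
    np.testing.assert_array_equal(again.means, model.means)
    np.testing.assert_array_equal(again.variances, model.variances)
    assert again.attribute_names == model.attribute_names


class TestFrequencyNB:
    def test_single_attribute_frequencies(self):
        X = np.array([[0], [0], [1], [1], [1], [0]])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        nb = FrequencyNB(X, y)
        assert nb.joint([1], 1) == pytest.approx(0.5 * (2 / 3))
        assert nb.joint([1], 0) == pytest.approx(0.5 * (1 / 3))
        assert nb.predict([1]) is True
        assert nb.predict([0]) is False

    def test_unseen_value_has_zero_likelihood(self):
        nb = FrequencyNB(np.array([[0], [1]]), np.array([False, True]))
        assert nb.joint([5], 0) == 0.0
        assert nb.predict([5]) is False  # 0 > 0 is false

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            FrequencyNB(np.array([[0], [1]]), np.array([True, True]))
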