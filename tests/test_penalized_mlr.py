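"""The MLR-EN core: objective pieces, solver correctness, CV selection."""

import numpy as np
import pytest
from scipy.special import softmax

from mirsel.penalized_mlr import (
    DimensionError,
    MlrModel,
    PenaltyConfig,
    elastic_net_penalty,
    fit_mlr_en,
    lambda_max,
    multinomial_log_likelihood,
    predict_class,
    predict_proba,
    select_params,
)

RNG = np.random.default_rng(42)
NO_STD = PenaltyConfig(standardize=False, convergence_tol=1e-10)


def zero_model(p=4, K=5):
    return MlrModel(
        coefficients=np.zeros((p, K)),
        intercepts=np.zeros(K),
        alpha0=0.5,
        lambda0=0.1,
        objective_value=0.0,
        classes=np.arange(1, K + 1),
    )


def random_fixture(n=20, p=5, K=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.integers(1, K + 1, size=n)
    y[:K] = np.arange(1, K + 1)  # every class represented
    return X, y


class TestLogLikelihood:
    def test_zero_model_gives_uniform_softmax(self):
        X, y = random_fixture()
        value = multinomial_log_likelihood(zero_model(p=5), X, y)
        assert np.isclose(value, -20 * np.log(5))

    def test_single_sample_matches_hand_computed_softmax(self):
        model = zero_model(p=2)
        model.intercepts = np.array([10.0, 0.0, 0.0, 0.0, 0.0])
        x = np.zeros((1, 2))
        expected = 10.0 - np.log(np.exp(10.0) + 4.0)
        assert np.isclose(
            multinomial_log_likelihood(model, x, np.array([1])), expected
        )

    def test_intercept_shift_invariance(self):
        X, y = random_fixture(seed=3)
        model = zero_model(p=5)
        model.coefficients = RNG.normal(size=(5, 5))
        model.intercepts = RNG.normal(size=5)
        before = multinomial_log_likelihood(model, X, y)
        model.intercepts = model.intercepts + 3.7
        assert np.isclose(multinomial_log_likelihood(model, X, y), before)

    def test_always_nonpositive(self):
        X, y = random_fixture(seed=9)
        model = zero_model(p=5)
        model.coefficients = RNG.normal(size=(5, 5))
        assert multinomial_log_likelihood(model, X, y) <= 0

    def test_dimension_mismatch_rejected(self):
        X, y = random_fixture()
        with pytest.raises(DimensionError):
            multinomial_log_likelihood(zero_model(p=3), X, y)


class TestPenalty:
    @pytest.mark.parametrize(
        "coefs, alpha, expected",
        [
            (np.zeros((4, 5)), 0.5, 0.0),
            (np.array([[2.0]]), 1.0, 2.0),  # pure L1
            (np.array([[2.0]]), 0.0, 2.0),  # ridge: 0.5 * 4
            (np.array([[2.0]]), 0.5, 2.0),  # 0.5*0.5*4 + 0.5*2
            (np.array([[-1.0, 3.0]]), 1.0, 4.0),
        ],
    )
    def test_closed_forms(self, coefs, alpha, expected):
        assert np.isclose(elastic_net_penalty(coefs, alpha), expected)


class TestFit:
    def test_lambda_max_zeroes_every_coefficient(self):
        X, y = random_fixture(n=40, seed=1)
        lmax = lambda_max(X, y, alpha=0.8)
        model = fit_mlr_en(X, y, alpha=0.8, lam=lmax * 1.01, config=NO_STD)
        assert np.all(model.coefficients == 0.0)
        # intercept-only model predicts training-class priors
        proba = predict_proba(model, X)
        _, counts = np.unique(y, return_counts=True)
        assert np.allclose(proba[0], counts / counts.sum(), atol=1e-4)

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X = np.array(
            [[-2.0, 0.0], [-3.0, 1.0], [-2.5, -1.0], [2.0, 0.0], [3.0, 1.0],
             [2.5, -1.0]]
        )
        y = np.array([1, 1, 1, 2, 2, 2])
        model = fit_mlr_en(X, y, alpha=0.5, lam=1e-4, config=NO_STD)
        assert np.mean(predict_class(model, X) == y) == 1.0

    def test_ridge_matches_sklearn_within_1e4(self):
        """α=0 agrees with an independent ridge-multinomial solver."""
        from sklearn.linear_model import LogisticRegression

        X, y = random_fixture(n=20, p=5, seed=7)
        lam = 0.1
        ours = fit_mlr_en(X, y, alpha=0.0, lam=lam, config=NO_STD)
        ref = LogisticRegression(
            C=1.0 / (X.shape[0] * lam), solver="lbfgs", tol=1e-12, max_iter=20000
        ).fit(X, y)
        assert np.abs(ours.coefficients - ref.coef_.T).max() < 1e-4
        assert np.abs(ours.intercepts - ref.intercept_).max() < 1e-4

    def test_unpenalized_reduces_to_plain_mlr(self):
        """λ=0 agrees with an unpenalized solver on a well-conditioned fixture."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        w_true = rng.normal(size=(3, 3))
        y = np.argmax(X @ w_true + rng.gumbel(size=(200, 3)), axis=1) + 1
        ours = fit_mlr_en(X, y, alpha=0.3, lam=0.0, config=NO_STD)
        ref = LogisticRegression(
            C=np.inf, solver="lbfgs", tol=1e-12, max_iter=20000
        ).fit(X, y)
        assert np.abs(ours.coefficients - ref.coef_.T).max() < 1e-3

    def test_kkt_subgradient_conditions_at_solution(self):
        """Zero coefficients satisfy |smooth gradient| ≤ λα; nonzero ones are
        stationary."""
        from mirsel.penalized_mlr import _nll_and_grad, _one_hot

        X, y = random_fixture(n=30, p=6, seed=11)
        alpha, lam = 0.6, 0.05
        model = fit_mlr_en(X, y, alpha, lam, config=NO_STD)
        W = model.coefficients
        Y = _one_hot(y, model.classes)
        _, gW, gb = _nll_and_grad(W, model.intercepts, X, Y)
        g_smooth = gW + lam * (1 - alpha) * W
        zero = W == 0.0
        assert (np.abs(g_smooth[zero]) <= lam * alpha + 1e-5).all()
        resid = g_smooth[~zero] + lam * alpha * np.sign(W[~zero])
        assert np.abs(resid).max() < 1e-5
        assert np.abs(gb).max() < 1e-6  # intercepts unpenalized

    def test_smooth_loss_monotone_along_lambda_path(self):
        from mirsel.penalized_mlr import _nll_and_grad, _one_hot

        X, y = random_fixture(n=40, p=6, seed=13)
        losses = []
        for lam in (0.3, 0.1, 0.03, 0.01):
            model = fit_mlr_en(X, y, alpha=0.5, lam=lam, config=NO_STD)
            Y = _one_hot(y, model.classes)
            nll, _, _ = _nll_and_grad(
                model.coefficients, model.intercepts, X, Y
            )
            losses.append(nll)
        # smaller λ fits the smooth part at least as well
        assert all(b <= a + 1e-8 for a, b in zip(losses, losses[1:]))

    def test_standardized_fit_reports_original_scale_coefficients(self):
        X, y = random_fixture(n=50, p=4, seed=17)
        X[:, 0] *= 100.0  # wildly different scales
        model = fit_mlr_en(X, y, alpha=0.0, lam=0.01)
        proba_direct = softmax(
            X @ model.coefficients + model.intercepts, axis=1
        )
        assert np.allclose(predict_proba(model, X), proba_direct)


class TestSelectParams:
    def test_single_alpha_grid_returns_it(self):
        X, y = random_fixture(n=30, seed=2)
        config = PenaltyConfig(
            alpha_grid=(0.4,), lambda_path_length=5, cv_folds=3,
            convergence_tol=1e-6,
        )
        alpha0, _ = select_params(X, y, config, seed=1)
        assert alpha0 == 0.4

    def test_deterministic_given_seed(self):
        X, y = random_fixture(n=40, seed=4)
        config = PenaltyConfig(
            alpha_grid=(0.2, 0.8), lambda_path_length=6, cv_folds=3,
            convergence_tol=1e-6,
        )
        assert select_params(X, y, config, seed=5) == select_params(
            X, y, config, seed=5
        )

    def test_pure_noise_keeps_null_model_competitive(self):
        """On pure noise, CV deviance at λ_max is within one SE of the minimum."""
        rng = np.random.default_rng(23)
        X = rng.normal(size=(100, 10))
        y = np.tile(np.arange(1, 6), 20)
        config = PenaltyConfig(
            alpha_grid=(0.5,), lambda_path_length=8, cv_folds=5,
            convergence_tol=1e-7,
        )
        _, _, table = select_params(X, y, config, seed=9, full_output=True)
        dev = table.mean_deviance[0]
        i_min = dev.argmin()
        assert dev[0] <= dev[i_min] + table.se_deviance[0, i_min]


class TestPrediction:
    def test_zero_model_predicts_uniform(self):
        proba = predict_proba(zero_model(p=3), np.zeros((4, 3)))
        assert np.allclose(proba, 0.2)

    def test_rows_sum_to_one_and_argmax_consistent(self):
        model = zero_model(p=4)
        model.coefficients = RNG.normal(size=(4, 5))
        model.intercepts = RNG.normal(size=5)
        X = RNG.normal(size=(30, 4))
        proba = predict_proba(model, X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(
            predict_class(model, X), model.classes[np.argmax(proba, axis=1)]
        )

    def test_tie_breaks_to_smallest_class(self):
        proba = predict_proba(zero_model(p=2), np.zeros((3, 2)))
        assert np.allclose(proba, 0.2)
        assert (predict_class(zero_model(p=2), np.zeros((3, 2))) == 1).all()
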