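import numpy as np
import pytest
from scipy.optimize import minimize

from resptex.classifier import (ConvergenceWarning, RidgeLogisticModel,
                                fit_dfp, gradient, penalized_loglik)


def literal_loglik(theta, X, y, lam):
    """Summation oracle: term-by-term log-likelihood minus ridge penalty."""
    total = 0.0
    for xi, yi in zip(X, y):
        g = theta[0] + float(np.dot(theta[1:], xi))
        p = 1.0 / (1.0 + np.exp(-g))
        total += yi * np.log(p) + (1 - yi) * np.log(1 - p)
    return total - lam * float(np.sum(theta[1:] ** 2))


def simulate_logistic(rng, n, d, theta_true):
    X = rng.normal(size=(n, d))
    p = 1.0 / (1.0 + np.exp(-(theta_true[0] + X @ theta_true[1:])))
    y = (rng.uniform(size=n) < p).astype(int)
    return X, y


def scipy_optimum(X, y, lam):
    d = X.shape[1] + 1
    res = minimize(lambda t: -penalized_loglik(t, X, y, lam),
                   np.zeros(d),
                   jac=lambda t: -gradient(t, X, y, lam), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return -res.fun, res.x


class TestPenalizedLoglik:
    def test_zero_theta_closed_form(self, rng):
        X, y = rng.normal(size=(12, 3)), np.array([0, 1] * 6)
        assert penalized_loglik(np.zeros(4), X, y, 0.5) == \
            pytest.approx(12 * np.log(0.5))

    def test_lambda_zero_is_unpenalized(self, rng):
        X, y = rng.normal(size=(10, 3)), np.array([0, 1] * 5)
        theta = rng.normal(size=4)
        assert penalized_loglik(theta, X, y, 0.0) == \
            pytest.approx(literal_loglik(theta, X, y, 0.0), abs=1e-12)

    def test_matches_literal_summation(self, rng):
        X, y = rng.normal(size=(20, 3)), np.array([0, 1] * 10)
        theta = rng.normal(size=4)
        assert penalized_loglik(theta, X, y, 0.3) == \
            pytest.approx(literal_loglik(theta, X, y, 0.3), abs=1e-12)

    def test_norm_penalty_form(self, rng):
        X, y = rng.normal(size=(10, 2)), np.array([0, 1] * 5)
        theta = np.array([0.5, 2.0, -1.0])
        diff = penalized_loglik(theta, X, y, 0.7, penalty_form="squared") \
            - penalized_loglik(theta, X, y, 0.7, penalty_form="norm")
        assert diff == pytest.approx(-0.7 * (5.0 - np.sqrt(5.0)))

    def test_non_binary_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            penalized_loglik(np.zeros(3), rng.normal(size=(4, 2)),
                             np.array([0, 1, 2, 1]))


class TestGradient:
    def test_matches_central_differences(self, rng):
        for _ in range(3):
            X, y = rng.normal(size=(15, 4)), rng.integers(0, 2, 15)
            if len(np.unique(y)) < 2:
                continue
            theta = rng.normal(size=5)
            g = gradient(theta, X, y, 0.2)
            eps = 1e-6
            for j in range(5):
                e = np.zeros(5)
                e[j] = eps
                fd = (penalized_loglik(theta + e, X, y, 0.2)
                      - penalized_loglik(theta - e, X, y, 0.2)) / (2 * eps)
                assert g[j] == pytest.approx(fd, abs=1e-6)

    def test_stationary_at_symmetric_optimum(self):
        # balanced symmetric data: theta = 0 maximizes the likelihood
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([0, 1, 1, 0])
        g = gradient(np.zeros(2), X, y, 0.0)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_large_lambda_shrink_direction(self):
        X = np.array([[0.1], [0.2]])
        y = np.array([0, 1])
        theta = np.array([0.0, 5.0])
        g = gradient(theta, X, y, 1e6)
        # ridge term -2*lambda*theta dominates the non-intercept entry
        assert g[1] == pytest.approx(-2e6 * 5.0, rel=1e-3)
        # intercept is unpenalized
        assert abs(g[0]) < 10


class TestFitDfp:
    def test_1d_toy_decision_boundary(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_dfp(X, y, lam=1e-8, standardize=False)
        assert model.theta[1] > 0
        boundary = -model.theta[0] / model.theta[1]
        assert abs(boundary) < 0.5
        f_dfp = penalized_loglik(model.theta, X, y, 1e-8)
        f_ref, _ = scipy_optimum(X, y, 1e-8)
        assert f_dfp == pytest.approx(f_ref, abs=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_dfp(rng.normal(size=(6, 2)), np.ones(6))

    @pytest.mark.parametrize("lam", [1e-8, 0.01, 1.0])
    def test_objective_matches_independent_optimizer(self, lam, rng):
        for _ in range(4):
            theta_true = rng.normal(size=4)
            X, y = simulate_logistic(rng, 60, 3, theta_true)
            if len(np.unique(y)) < 2:
                continue
            model = fit_dfp(X, y, lam=lam, standardize=False)
            f_dfp = penalized_loglik(model.theta, X, y, lam)
            f_ref, _ = scipy_optimum(X, y, lam)
            assert f_dfp == pytest.approx(f_ref, abs=1e-6)

    def test_parameter_recovery_within_3_se(self, rng):
        n, d = 500, 16
        theta_true = np.concatenate([[0.2], rng.normal(0, 0.7, d)])
        X, y = simulate_logistic(rng, n, d, theta_true)
        model = fit_dfp(X, y, lam=1e-8, standardize=False)
        Xd = np.hstack([np.ones((n, 1)), X])
        p = 1.0 / (1.0 + np.exp(-(Xd @ model.theta)))
        cov = np.linalg.inv(Xd.T @ (Xd * (p * (1 - p))[:, None]))
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(model.theta - theta_true) < 3 * se)

    def test_monotone_ascent(self, rng):
        # re-run the iteration by hand, checking objective never decreases
        theta_true = rng.normal(size=5)
        X, y = simulate_logistic(rng, 80, 4, theta_true)
        lam = 0.01
        values = []
        import warnings
        with warnings.catch_warnings():
            # tol=0 forces a stop at max_iter by construction
            warnings.simplefilter("ignore", ConvergenceWarning)
            for it in range(1, 30):
                m = fit_dfp(X, y, lam=lam, standardize=False, max_iter=it,
                            tol=0.0)
                values.append(penalized_loglik(m.theta, X, y, lam))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_lambda_limits(self, rng):
        theta_true = np.array([0.1, 1.5, -1.0])
        X, y = simulate_logistic(rng, 200, 2, theta_true)
        ml = fit_dfp(X, y, lam=0.0, standardize=False)
        tiny = fit_dfp(X, y, lam=1e-10, standardize=False)
        np.testing.assert_allclose(tiny.theta, ml.theta, atol=1e-4)
        huge = fit_dfp(X, y, lam=1e6, standardize=False)
        np.testing.assert_allclose(huge.theta[1:], 0.0, atol=1e-4)

    def test_secant_condition_after_each_update(self, rng):
        # replicate the DFP update loop, asserting H @ y = d at 1e-8
        from resptex.classifier import _design
        theta_true = rng.normal(size=4)
        X, y = simulate_logistic(rng, 50, 3, theta_true)
        lam = 0.05
        d_dim = 4
        theta = np.zeros(d_dim)
        H = np.eye(d_dim)
        g = gradient(theta, X, y, lam)
        for _ in range(15):
            p = H @ g
            if g @ p <= 0:
                H, p = np.eye(d_dim), g.copy()
            a, f = 1.0, penalized_loglik(theta, X, y, lam)
            while penalized_loglik(theta + a * p, X, y, lam) < \
                    f + 1e-4 * a * (g @ p):
                a *= 0.5
            step = a * p
            theta_new = theta + step
            g_new = gradient(theta_new, X, y, lam)
            yv = g - g_new
            if step @ yv > 1e-12:
                Hy = H @ yv
                H = H + np.outer(step, step) / (step @ yv) \
                    - np.outer(Hy, Hy) / (yv @ Hy)
                np.testing.assert_allclose(H @ yv, step, atol=1e-8)
                np.testing.assert_allclose(H, H.T, atol=1e-12)
            theta, g = theta_new, g_new

    def test_agrees_with_sklearn_ridge_logistic(self, rng):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        theta_true = rng.normal(size=6)
        X, y = simulate_logistic(rng, 120, 5, theta_true)
        lam = 0.1
        model = fit_dfp(X, y, lam=lam, standardize=False)
        # sklearn minimizes sum(loss) + 1/(2C) ||w||^2  ->  C = 1/(2*lambda)
        clf = sklearn_linear.LogisticRegression(
            C=1.0 / (2.0 * lam), tol=1e-10, max_iter=5000)
        clf.fit(X, y)
        theta_sk = np.concatenate([clf.intercept_, clf.coef_[0]])
        f_ours = penalized_loglik(model.theta, X, y, lam)
        f_sk = penalized_loglik(theta_sk, X, y, lam)
        assert f_ours == pytest.approx(f_sk, abs=1e-6)

    def test_perfect_separation_guarded(self, rng):
        # at lambda=0 the ML weights of separated classes are unbounded;
        # the iteration cap keeps the estimate finite, and a positive
        # ridge pulls it back to moderate magnitude
        X = np.concatenate([rng.normal(-5, 0.1, 20), rng.normal(5, 0.1, 20)])
        y = np.repeat([0, 1], 20)
        unpenalized = fit_dfp(X[:, None], y, lam=0.0, standardize=False,
                              max_iter=50)
        assert np.all(np.isfinite(unpenalized.theta))
        ridged = fit_dfp(X[:, None], y, lam=1.0, standardize=False)
        assert abs(ridged.theta[1]) < abs(unpenalized.theta[1]) / 10


class TestPredict:
    def test_zero_theta_gives_half(self, rng):
        model = RidgeLogisticModel(np.zeros(3), 1e-8, ["a", "b"],
                                   np.zeros(2), np.ones(2))
        p = model.predict_proba(rng.normal(size=(5, 2)))
        np.testing.assert_array_equal(p, 0.5)
        np.testing.assert_array_equal(model.predict(rng.normal(size=(5, 2))),
                                      1)  # p >= 0.5 -> class 1

    def test_matches_hand_sigmoid(self, rng):
        theta = rng.normal(size=4)
        means, scales = rng.normal(size=3), rng.uniform(0.5, 2.0, 3)
        model = RidgeLogisticModel(theta, 1e-8, ["a", "b", "c"], means, scales)
        X = rng.normal(size=(10, 3))
        Z = (X - means) / scales
        expected = 1.0 / (1.0 + np.exp(-(theta[0] + Z @ theta[1:])))
        np.testing.assert_allclose(model.predict_proba(X), expected,
                                   atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        model = RidgeLogisticModel(np.zeros(3), 1e-8, ["a", "b"],
                                   np.zeros(2), np.ones(2))
        with pytest.raises(ValueError, match="expects 2 features"):
            model.predict(rng.normal(size=(4, 5)))

    def test_json_round_trip(self, rng):
        theta_true = np.array([0.5, 1.0, -2.0])
        X, y = simulate_logistic(rng, 100, 2, theta_true)
        model = fit_dfp(X, y, lam=1e-4)
        back = RidgeLogisticModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.theta, model.theta)
        np.testing.assert_array_equal(back.predict_proba(X),
                                      model.predict_proba(X))
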