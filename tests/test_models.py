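"""Univariate, PLS and neural-network diagnostic models."""

import numpy as np
import pytest

from npkspec.evaluation import r_squared
from npkspec.models import (
    FeedforwardNetModel,
    fit_nn,
    fit_pls,
    fit_univariate,
    predict,
)


class TestUnivariate:
    def test_linear_exact_recovery(self):
        x = np.linspace(0, 10, 20)
        res = fit_univariate(x, 2 * x + 1, family="linear")
        assert res.params["a"] == pytest.approx(1.0, abs=1e-10)
        assert res.params["b"] == pytest.approx(2.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0)

    def test_parabola_interpolates_three_points(self):
        x = np.array([-1.0, 0.0, 2.0])
        res = fit_univariate(x, x**2, family="parabolic")
        assert res.params["a"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["b"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["c"] == pytest.approx(1.0, abs=1e-10)

    def test_exponential_noiseless_recovery(self):
        x = np.linspace(0, 4, 25)
        res = fit_univariate(x, 3.0 * np.exp(0.5 * x), family="exponential")
        assert res.params["a"] == pytest.approx(3.0, abs=1e-6)
        assert res.params["b"] == pytest.approx(0.5, abs=1e-6)

    def test_logarithmic_noiseless_recovery(self):
        x = np.linspace(0.5, 8, 30)
        res = fit_univariate(x, 1.5 + 0.7 * np.log(x), family="logarithmic")
        assert res.params["a"] == pytest.approx(1.5, abs=1e-10)
        assert res.params["b"] == pytest.approx(0.7, abs=1e-10)

    @pytest.mark.parametrize("family,a,b,c", [
        ("linear", 1.2, -0.8, None),
        ("parabolic", 0.5, 1.1, -0.2),
        ("exponential", 2.0, 0.3, None),
        ("logarithmic", -1.0, 2.2, None),
    ])
    def test_self_generated_data_refit_recovers_coefficients(self, family, a, b, c):
        x = np.linspace(0.3, 5.0, 40)
        if family == "linear":
            y = a + b * x
        elif family == "parabolic":
            y = a + b * x + c * x**2
        elif family == "exponential":
            y = a * np.exp(b * x)
        else:
            y = a + b * np.log(x)
        res = fit_univariate(x, y, family=family)
        for key, val in (("a", a), ("b", b), ("c", c)):
            if val is not None:
                assert res.params[key] == pytest.approx(val, rel=1e-4)

    def test_domain_violations_name_offenders(self):
        x = np.array([1.0, -2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_univariate(x, np.abs(x), family="logarithmic")
        with pytest.raises(ValueError, match="y > 0"):
            fit_univariate(np.arange(4.0), x, family="exponential")

    def test_predict_evaluates_stored_form(self):
        res = fit_univariate(np.arange(5.0), 1 + 2 * np.arange(5.0), family="linear")
        assert predict(res, np.array([3.0]))[0] == pytest.approx(7.0)
        with pytest.raises(ValueError, match="x > 0"):
            fit_univariate(np.linspace(1, 5, 10),
                           np.log(np.linspace(1, 5, 10)) + 1,
                           family="logarithmic").predict(np.array([-1.0]))

    def test_fit_invariant_to_sample_order(self, rng):
        x = rng.uniform(0.5, 5, 30)
        y = 2 + 0.5 * x + rng.normal(0, 0.1, 30)
        perm = rng.permutation(30)
        a = fit_univariate(x, y, family="linear").params
        b = fit_univariate(x[perm], y[perm], family="linear").params
        assert a["a"] == pytest.approx(b["a"], rel=1e-10)
        assert a["b"] == pytest.approx(b["b"], rel=1e-10)

    def test_equation_string_mentions_predictor(self):
        res = fit_univariate(np.arange(5.0), np.arange(5.0) * 3,
                             family="linear", predictor_name="Rr")
        assert "Rr" in res.equation()
        assert "R^2" in res.summary()


class TestPLS:
    def test_full_components_equal_least_squares(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        res = fit_pls(X, y, n_components=3)
        A = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(res.coefs, beta[1:], atol=1e-8)
        np.testing.assert_allclose(res.predict(X), A @ beta, atol=1e-8)

    def test_constant_response_gives_zero_slopes(self, rng):
        X = rng.normal(size=(20, 3))
        res = fit_pls(X, np.full(20, 5.0), n_components=2)
        np.testing.assert_array_equal(res.coefs, 0.0)
        assert res.intercept == pytest.approx(5.0)

    def test_prediction_at_column_means_is_mean_response(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        res = fit_pls(X, y, n_components=2)
        assert res.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        col = rng.normal(size=20)
        X = np.column_stack([col, col, col])
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, rng.normal(size=20), n_components=3)

    def test_fit_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(24, 3))
        y = rng.normal(size=24)
        perm = rng.permutation(24)
        a = fit_pls(X, y, n_components=2)
        b = fit_pls(X[perm], y[perm], n_components=2)
        np.testing.assert_allclose(a.coefs, b.coefs, atol=1e-10)

    def test_equation_in_linear_combination_form(self, rng):
        X = rng.normal(size=(15, 3))
        res = fit_pls(X, rng.normal(size=15), n_components=2,
                      predictor_names=["Xdb3-D4-448", "Xdb3-D4-450", "Xdb2-D5-367"])
        assert "Xdb3-D4-448" in res.equation()
        assert res.equation().startswith("Y = ")


class TestNeuralNet:
    def test_learns_linear_target(self, rng):
        X = rng.uniform(size=(60, 3))
        y = 1.0 + X @ np.array([2.0, -1.0, 0.5]) + rng.normal(0, 0.005, 60)
        res = fit_nn(X, y, seed=0)
        assert res.rsquared > 0.99

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(size=(40, 3))
        y = X.sum(axis=1)
        a = fit_nn(X, y, seed=7)
        b = fit_nn(X, y, seed=7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_pure_noise_target_has_no_validation_skill(self):
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(60, 3))
            y = rng.normal(size=60)
            res = fit_nn(X[:40], y[:40], seed=seed)
            r2s.append(r_squared(y[40:], res.predict(X[40:]), method="corr"))
        assert np.median(r2s) < 0.3

    def test_predict_matches_manual_forward_pass(self, rng):
        X = rng.uniform(size=(30, 3))
        y = X @ np.array([1.0, 2.0, 3.0])
        res = fit_nn(X, y, seed=1)
        z = (X - res.x_min) / res.x_range
        hidden = 1.0 / (1.0 + np.exp(-(z @ res.weights[0] + res.biases[0])))
        out = hidden @ res.weights[1] + res.biases[1]
        manual = out.ravel() * res.y_range + res.y_min
        np.testing.assert_allclose(res.predict(X), manual, atol=1e-10)

    def test_non_finite_inputs_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            FeedforwardNetModel(X, np.ones(10))
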