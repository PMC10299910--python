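"""GLM kernel: closed-form oracles, statsmodels cross-checks, LRT/IC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import growthpaths.glm as glm
from growthpaths.exceptions import (RankDeficiencyError, SeparationError,
                                    ValidationError)


def _design(y, X, cols, family):
    return glm.DesignMatrix(np.asarray(y, float), np.asarray(X, float), cols, family)


def _with_intercept(x):
    x = np.asarray(x, float)
    return np.column_stack([np.ones(len(x)), x])


class TestGaussian:
    def test_perfect_fit(self):
        x = np.arange(5.0)
        fit = glm.fit_gaussian(_design(2 * x, _with_intercept(x), ["intercept", "x"], "gaussian"))
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.scale == pytest.approx(0.0, abs=1e-20)
        assert np.isfinite(fit.loglik)

    def test_three_point_normal_equations(self):
        # points (0,1), (1,3), (2,4): closed form slope 1.5, intercept 7/6
        x = [0.0, 1.0, 2.0]
        y = [1.0, 3.0, 4.0]
        fit = glm.fit_gaussian(_design(y, _with_intercept(x), ["intercept", "x"], "gaussian"))
        assert fit.params["x"] == pytest.approx(1.5, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(7.0 / 6.0, abs=1e-12)

    def test_constant_response(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = glm.fit_gaussian(_design(np.full(4, 2.5), _with_intercept(x),
                                       ["intercept", "x"], "gaussian"))
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(2.5)

    def test_matches_statsmodels_ols(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 60))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            y = X @ rng.normal(size=4) + rng.normal(size=n)
            fit = glm.fit_gaussian(_design(y, X, list("abcd"), "gaussian"))
            ref = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit.params.to_numpy(), ref.params, rtol=1e-8)
            np.testing.assert_allclose(fit.se.to_numpy(), ref.bse, rtol=1e-8)
            # statsmodels OLS llf also uses the ML variance estimate
            assert fit.loglik == pytest.approx(ref.llf, rel=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(RankDeficiencyError, match="collinear"):
            glm.fit_gaussian(_design(rng.normal(size=20), X,
                                     ["intercept", "x", "x_twice"], "gaussian"))


def _grouped_2x2(a, b, c, d):
    """Individual rows for an exposure x outcome 2x2 table (a=e+o+, b=e+o-, ...)."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return _design(y, _with_intercept(x), ["intercept", "exposed"], "logit")


class TestLogistic:
    def test_2x2_log_odds_ratio(self):
        fit = glm.fit_logistic(_grouped_2x2(10, 20, 30, 40))
        assert fit.params["exposed"] == pytest.approx(np.log(10 * 40 / (20 * 30)), abs=1e-6)

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_2x2_oracle_random_tables(self, cells):
        a, b, c, d = cells
        fit = glm.fit_logistic(_grouped_2x2(a, b, c, d))
        assert fit.params["exposed"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_intercept_only_is_logit_of_mean(self):
        y = np.array([1, 1, 0, 0, 0], float)
        fit = glm.fit_logistic(_design(y, np.ones((5, 1)), ["intercept"], "logit"))
        assert fit.params["intercept"] == pytest.approx(np.log(0.4 / 0.6), abs=1e-8)

    def test_symmetry_flip(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = glm.fit_logistic(_design(y, _with_intercept(x), ["intercept", "x"], "logit"))
        flipped = glm.fit_logistic(_design(1 - y, _with_intercept(-x),
                                           ["intercept", "x"], "logit"))
        assert flipped.params["x"] == pytest.approx(fit.params["x"], abs=1e-7)
        assert flipped.params["intercept"] == pytest.approx(-fit.params["intercept"], abs=1e-7)

    def test_matches_statsmodels_logit(self, rng):
        for _ in range(10):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            eta = X @ np.array([-0.3, 0.7, -0.5])
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = glm.fit_logistic(_design(y, X, list("abc"), "logit"))
            ref = sm.Logit(y, X).fit(disp=0)
            np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
            np.testing.assert_allclose(fit.se.to_numpy(), ref.bse, rtol=1e-5)
            assert fit.loglik == pytest.approx(ref.llf, rel=1e-9)

    def test_se_matches_finite_difference_hessian(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        eta = X @ np.array([0.2, -0.6, 0.9])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = glm.fit_logistic(_design(y, X, list("abc"), "logit"))

        def ll(beta):
            e = X @ beta
            return y @ e - np.logaddexp(0, e).sum()

        beta = fit.params.to_numpy()
        h = 1e-5
        p = len(beta)
        hess = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                ei, ej = np.eye(p)[i] * h, np.eye(p)[j] * h
                hess[i, j] = (ll(beta + ei + ej) - ll(beta + ei - ej)
                              - ll(beta - ei + ej) + ll(beta - ei - ej)) / (4 * h * h)
        se_num = np.sqrt(np.diag(np.linalg.inv(-hess)))
        np.testing.assert_allclose(fit.se.to_numpy(), se_num, rtol=1e-4)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError, match="single value"):
            glm.fit_logistic(_design(np.ones(10), np.ones((10, 1)), ["intercept"], "logit"))

    def test_separation_raises(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError, match="separated"):
            glm.fit_logistic(_design(y, _with_intercept(x), ["intercept", "x"], "logit"))

    def test_ridge_fallback_handles_separation(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = (x > 0).astype(float)
        fit = glm.fit_logistic(_design(y, _with_intercept(x), ["intercept", "x"], "logit"),
                               ridge=1e-2)
        assert np.isfinite(fit.params["x"])


def _fake_fit(loglik, n_params, n, family="gaussian", cols=("intercept",)):
    s = pd.Series(np.zeros(len(cols)), index=list(cols))
    return glm.EquationFit(name="fake", family=family, params=s, se=s + 1.0,
                           cov=np.eye(len(cols)), loglik=loglik, scale=1.0,
                           n=n, n_params=n_params, n_iter=1, grad_norm=0.0)


class TestCriteriaAndLRT:
    def test_information_criteria_arithmetic(self):
        aic, bic = glm.information_criteria(_fake_fit(-100.0, 3, 100))
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200.0 + 3 * np.log(100))

    def test_zero_parameters_rejected(self):
        with pytest.raises(ValidationError):
            glm.information_criteria(_fake_fit(-1.0, 0, 10))

    def test_chi_square_reference(self):
        null = _fake_fit(-100.0, 2, 50, cols=("intercept", "a"))
        alt = _fake_fit(-100.0 + 3.84 / 2, 3, 50, cols=("intercept", "a", "b"))
        stat, df, p = glm.likelihood_ratio_test(null, alt)
        assert stat == pytest.approx(3.84)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_df_rejected(self):
        fit = _fake_fit(-10.0, 2, 30)
        with pytest.raises(ValidationError):
            glm.likelihood_ratio_test(fit, fit)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValidationError, match="same n"):
            glm.likelihood_ratio_test(_fake_fit(-10.0, 2, 30),
                                      _fake_fit(-9.0, 3, 40, cols=("intercept", "a", "b")))

    def test_noise_column_lrt_near_zero(self, rng):
        """An extra pure-noise column never decreases -2loglik; LRT ~ small."""
        n = 80
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        base = glm.fit_gaussian(_design(y, _with_intercept(x), ["intercept", "x"], "gaussian"))
        X2 = np.column_stack([_with_intercept(x), rng.normal(size=n)])
        alt = glm.fit_gaussian(_design(y, X2, ["intercept", "x", "noise"], "gaussian"))
        stat, df, p = glm.likelihood_ratio_test(base, alt)
        assert stat >= 0.0
        assert df == 1
        assert 0.0 <= p <= 1.0
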