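"""Estimator families: closed forms, MLE behaviour, equivalences,
bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.tools import numdiff

from cfqrmap import estimators as est


def _design(rng, n, k=2):
    X = pd.DataFrame({f"x{i}": rng.uniform(0, 2, n) for i in range(k)})
    X["const"] = 1.0
    return X


class TestOLS:
    def test_exact_interpolation_without_noise(self):
        rng = np.random.default_rng(0)
        X = _design(rng, 200)
        y = 0.3 * X["x0"] - 0.1 * X["x1"] + 0.5
        res = est.fit_ols(X, y)
        assert res.params["x0"] == pytest.approx(0.3, abs=1e-10)
        assert res.params["const"] == pytest.approx(0.5, abs=1e-10)
        assert res.extra["r2"] == pytest.approx(1.0)

    def test_intercept_only_is_the_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.6, 0.2, 100)
        X = pd.DataFrame({"const": np.ones(100)})
        assert est.fit_ols(X, y).params["const"] == pytest.approx(y.mean())

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        X = _design(rng, 100)
        X["dup"] = X["x0"]
        with pytest.raises(est.CollinearityError, match="dup|x0"):
            est.fit_ols(X, rng.normal(size=100))

    def test_needs_more_rows_than_columns(self):
        X = pd.DataFrame({"x0": [1.0, 2.0], "const": 1.0})
        with pytest.raises(est.DataError):
            est.fit_ols(X, [0.1, 0.2])


class TestTobit:
    def test_matches_ols_when_nothing_censored(self):
        rng = np.random.default_rng(3)
        X = _design(rng, 800)
        y = 0.2 + 0.3 * X["x0"] + 0.1 * rng.standard_normal(800) - 2.0
        ols = est.fit_ols(X, y)
        tob = est.fit_tobit(X, y, upper=1.0)
        assert tob.extra["n_censored"] == 0
        assert np.max(np.abs(tob.params[X.columns] - ols.params)) < 1e-4

    def test_recovers_slope_under_censoring_where_ols_attenuates(self):
        rng = np.random.default_rng(4)
        n = 4000
        X = _design(rng, n, k=1)
        ystar = 0.2 + 0.5 * X["x0"] + 0.3 * rng.standard_normal(n)
        y = np.minimum(ystar, 1.0)
        assert 0.2 < (y == 1.0).mean() < 0.4
        tob = est.fit_tobit(X, y)
        ols = est.fit_ols(X, y)
        assert tob.params["x0"] == pytest.approx(0.5, abs=3 * tob.bse["x0"])
        assert ols.params["x0"] < 0.5 - 3 * ols.bse["x0"]

    def test_analytic_score_matches_numeric_gradient_and_vanishes(self):
        rng = np.random.default_rng(5)
        n = 500
        X = _design(rng, n, k=1)
        y = np.minimum(0.4 + 0.4 * X["x0"] + 0.25 * rng.standard_normal(n), 1.0)
        model = est.TobitMapper(y, X)
        theta = np.array([0.3, 0.3, np.log(0.3)])
        numeric = numdiff.approx_fprime(theta, model.loglike, centered=True)
        assert np.allclose(model.score(theta), numeric, rtol=1e-5, atol=1e-5)
        fitted = model.fit()
        at_opt = model.score(np.r_[fitted.params[X.columns].to_numpy(),
                                   np.log(fitted.extra["sigma"])])
        assert np.max(np.abs(at_opt)) < 1e-3

    def test_all_censored_not_identifiable(self):
        X = pd.DataFrame({"const": np.ones(20)})
        with pytest.raises(est.DataError):
            est.fit_tobit(X, np.ones(20))

    def test_censored_expectation_prediction_respects_the_limit(self):
        rng = np.random.default_rng(6)
        n = 1000
        X = _design(rng, n, k=1)
        y = np.minimum(0.5 + 0.5 * X["x0"] + 0.3 * rng.standard_normal(n), 1.0)
        res = est.fit_tobit(X, y)
        assert res.predict().max() <= 1.0
        assert res.predict(mode="latent").max() > 1.0


class TestTruncated:
    def test_wide_bounds_match_ols(self):
        rng = np.random.default_rng(7)
        X = _design(rng, 600)
        y = 0.1 + 0.2 * X["x0"] + 0.1 * rng.standard_normal(600)
        ols = est.fit_ols(X, y)
        tr = est.fit_truncated(X, y, bounds=(-100, 100))
        assert np.max(np.abs(tr.params[X.columns] - ols.params)) < 1e-6

    def test_loglike_at_optimum_dominates_ols_start(self):
        rng = np.random.default_rng(8)
        n = 1500
        X = _design(rng, n, k=1)
        y = 0.3 + 0.3 * X["x0"] + 0.3 * rng.standard_normal(n)
        keep = (y > -0.594) & (y < 0.99)
        model = est.TruncatedMapper(y[keep], X[keep])
        res = model.fit()
        theta = np.r_[res.params[X.columns], res.params["log_sigma"]]
        assert model.loglike(theta) >= model.loglike(model._start()) - 1e-9

    def test_data_outside_bounds_rejected(self):
        X = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(est.DataError):
            est.fit_truncated(X, np.linspace(0, 2, 10), bounds=(-0.594, 0.99))

    def test_conditional_mean_mode_shrinks_toward_interval(self):
        rng = np.random.default_rng(9)
        n = 2000
        X = _design(rng, n, k=1)
        y = 0.6 + 0.4 * X["x0"] + 0.3 * rng.standard_normal(n)
        keep = (y > -0.594) & (y < 0.99)
        res = est.fit_truncated(X[keep], y[keep])
        cond = res.predict(mode="conditional")
        assert cond.max() < 0.99
        assert res.predict().max() > cond.max()


class TestLogit:
    def test_intercept_only_closed_form(self):
        z = np.zeros(1000)
        z[:190] = 1.0
        X = pd.DataFrame({"const": np.ones(1000)})
        res = est.fit_logit(X, z)
        assert res.params["const"] == pytest.approx(np.log(0.19 / 0.81),
                                                    abs=1e-6)

    def test_uninformative_predictor_has_zero_slope(self):
        rng = np.random.default_rng(10)
        n = 3000
        X = _design(rng, n, k=1)
        z = (rng.random(n) < 0.5).astype(float)
        res = est.fit_logit(X, z)
        assert abs(res.params["x0"]) < 3 * res.bse["x0"] + 0.1

    def test_simulated_recovery(self):
        rng = np.random.default_rng(11)
        n = 5000
        X = _design(rng, n, k=1)
        eta = -1.0 + 1.5 * X["x0"]
        z = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = est.fit_logit(X, z)
        assert res.params["x0"] == pytest.approx(1.5, abs=3 * res.bse["x0"])

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        z = np.r_[np.zeros(20), np.ones(20)]
        X = pd.DataFrame({"x0": x, "const": 1.0})
        with pytest.raises(est.SeparationError):
            est.fit_logit(X, z)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(est.DataError):
            est.fit_logit(X, np.ones(10))


class TestTwoPart:
    @pytest.mark.parametrize("p,yhat,expected", [
        (1.0, -0.3, 1.0), (0.0, 0.5, 0.5), (0.4, 0.7, 0.82),
    ])
    def test_ev_formula(self, p, yhat, expected):
        assert est.tpm_predict(p, yhat) == pytest.approx(expected)

    def test_ev_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            est.tpm_predict(1.2, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(-0.594, 0.99))
    def test_ev_monotone_and_bounded(self, p1, p2, yhat):
        lo, hi = sorted([p1, p2])
        assert est.tpm_predict(lo, yhat) <= est.tpm_predict(hi, yhat) + 1e-12
        assert est.tpm_predict(p1, yhat) <= 1.0 + 1e-12

    def test_fit_and_predict_full_sample(self, frame):
        X = pd.DataFrame({"physical": frame["physical"], "const": 1.0})
        res = est.fit_two_part(X, frame["utility"])
        ev = res.predict()
        assert len(ev) == len(frame)
        # convex combination: EV stays below 1 wherever part 2 predicts <= 1
        yhat2 = res.part2.predict(X)
        assert (ev[yhat2 <= 1.0] <= 1.0 + 1e-9).all()
        assert (ev >= np.minimum(yhat2, 1.0) - 1e-9).all()
        assert isinstance(res.aic, tuple) and len(res.aic) == 2

    def test_needs_both_classes(self):
        X = pd.DataFrame({"const": np.ones(30)})
        with pytest.raises(est.DataError):
            est.fit_two_part(X, np.full(30, 0.5))


class TestInformationCriteria:
    def test_bic_exceeds_aic_beyond_n_e_squared(self, frame):
        X = pd.DataFrame({"physical": frame["physical"], "const": 1.0})
        res = est.fit_ols(X, frame["utility"])
        assert res.nobs > np.e**2
        assert res.bic > res.aic
        assert res.aic == pytest.approx(2 * res.k_params - 2 * res.llf)
        assert res.bic == pytest.approx(
            res.k_params * np.log(res.nobs) - 2 * res.llf)


class TestBootstrap:
    @staticmethod
    def _mean_fit(df):
        return pd.Series({"mu": df["y"].mean()})

    def test_zero_variance_data_gives_zero_width_interval(self):
        d = pd.DataFrame({"y": np.full(30, 0.7)})
        out = est.bootstrap_bc(self._mean_fit, d, reps=50, seed=0)
        assert out.loc["mu", "se"] == 0.0
        assert (out.loc["mu", "ci_lower"] == out.loc["mu", "ci_upper"]
                == out.loc["mu", "estimate"])
        assert out.loc["mu", "estimate"] == pytest.approx(0.7)

    def test_median_unbiased_case_equals_percentile_interval(self):
        rng = np.random.default_rng(12)
        d = pd.DataFrame({"y": rng.normal(0, 1, 200)})
        out = est.bootstrap_bc(self._mean_fit, d, reps=400, seed=1)
        # z0 near zero -> BC interval near the plain percentile interval
        assert abs(out.loc["mu", "z0"]) < 0.2
        assert out.attrs["seed"] == 1 and out.attrs["reps"] == 400

    def test_se_matches_theory_for_the_mean(self):
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, 400)
        d = pd.DataFrame({"y": y})
        out = est.bootstrap_bc(self._mean_fit, d, reps=600, seed=2)
        theory = y.std(ddof=1) / np.sqrt(len(y))
        assert out.loc["mu", "se"] == pytest.approx(theory, rel=0.15)

    def test_interval_coverage_on_a_linear_model(self):
        """BC 95% intervals cover the true slope at about the nominal rate."""
        rng = np.random.default_rng(14)
        true = 0.4
        hits = 0
        reps_mc = 200

        def fit(df):
            x, y = df["x"].to_numpy(), df["y"].to_numpy()
            b = np.polyfit(x, y, 1)
            return pd.Series({"slope": b[0]})

        for i in range(reps_mc):
            x = rng.uniform(0, 1, 60)
            y = 0.1 + true * x + 0.2 * rng.standard_normal(60)
            out = est.bootstrap_bc(fit, pd.DataFrame({"x": x, "y": y}),
                                   reps=200, seed=1000 + i)
            if out.loc["slope", "ci_lower"] <= true <= out.loc["slope", "ci_upper"]:
                hits += 1
        cover = hits / reps_mc
        # binomial 3-sigma band around 0.95 at 200 replications
        assert 0.89 <= cover <= 0.995

    def test_excessive_failures_raise(self):
        def flaky(df):
            if df.index.duplicated().any():   # i.e. every bootstrap resample
                raise RuntimeError("boom")
            return pd.Series({"mu": df["y"].mean()})

        d = pd.DataFrame({"y": np.arange(10.0)})
        with pytest.raises(RuntimeError, match="resamples"):
            est.bootstrap_bc(flaky, d, reps=20, seed=0)


class TestParameterRecoveryScaling:
    @pytest.mark.parametrize("n", [500, 5000])
    def test_bias_shrinks_with_n(self, n):
        rng = np.random.default_rng(15)
        X = _design(rng, n, k=1)
        y = np.minimum(0.3 + 0.5 * X["x0"] + 0.3 * rng.standard_normal(n), 1.0)
        res = est.fit_tobit(X, y)
        tol = 6.0 / np.sqrt(n)
        assert res.params["x0"] == pytest.approx(0.5, abs=tol)
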