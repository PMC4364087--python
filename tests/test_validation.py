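"""Validation statistics: errors, ICC, VIF, misspecification tests, CV."""

import numpy as np
import pandas as pd
import pytest

from cfqrmap import estimators as est, validation as val


class TestPredictionErrors:
    def test_perfect_prediction(self):
        assert val.prediction_errors([0.1, 0.5], [0.1, 0.5]) == (0.0, 0.0)

    def test_constant_offset(self):
        obs = np.linspace(0, 1, 20)
        mse, rmse = val.prediction_errors(obs, obs + 0.1)
        assert rmse == pytest.approx(0.1)
        assert mse == pytest.approx(rmse**2)

    def test_hand_example(self):
        mse, rmse = val.prediction_errors([0.0, 1.0], [0.5, 0.5])
        assert (mse, rmse) == (0.25, 0.5)

    def test_empty_and_misaligned_rejected(self):
        with pytest.raises(ValueError):
            val.prediction_errors([], [])
        with pytest.raises(ValueError):
            val.prediction_errors([1.0], [1.0, 2.0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        obs, pred = rng.random(50), rng.random(50)
        perm = rng.permutation(50)
        assert val.prediction_errors(obs, pred)[1] == pytest.approx(
            val.prediction_errors(obs[perm], pred[perm])[1])


class TestICC:
    def test_identity_gives_one(self):
        x = np.linspace(0, 1, 30)
        assert val.icc_agreement(x, x) == pytest.approx(1.0)

    def test_shift_penalised_relative_to_pearson(self):
        rng = np.random.default_rng(1)
        obs = rng.random(100)
        pred = obs + 0.5
        assert np.corrcoef(obs, pred)[0, 1] == pytest.approx(1.0)
        assert val.icc_agreement(obs, pred) < 0.5

    def test_hand_worked_mean_squares_oracle(self):
        """n=6 table checked against direct two-way ANOVA arithmetic."""
        obs = np.array([0.1, 0.3, 0.5, 0.6, 0.8, 0.9])
        pred = np.array([0.2, 0.2, 0.6, 0.5, 0.7, 1.0])
        data = np.column_stack([obs, pred])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((data - data.mean(1)[:, None] - data.mean(0)[None, :] + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert val.icc_agreement(obs, pred) == pytest.approx(expected)

    def test_against_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        obs = rng.random(40)
        pred = 0.8 * obs + 0.1 + 0.05 * rng.standard_normal(40)
        long = pd.DataFrame({
            "target": np.tile(np.arange(40), 2),
            "rater": np.repeat(["obs", "pred"], 40),
            "score": np.concatenate([obs, pred]),
        })
        ref = pingouin.intraclass_corr(long, "target", "rater", "score")
        match = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[match, "ICC"].iloc[0]
        assert val.icc_agreement(obs, pred) == pytest.approx(icc2, abs=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            val.icc_agreement([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            val.icc_agreement(np.ones(10), np.ones(10))


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2)})
        out = val.vif(X)
        assert out["vif"].max() == pytest.approx(1.0, abs=1e-8)
        assert not out["flag"].any()

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(3)
        x = rng.random(50)
        out = val.vif(pd.DataFrame({"a": x, "b": x, "c": rng.random(50)}))
        assert np.isinf(out.loc["a", "vif"]) and out.loc["a", "flag"]

    def test_near_collinearity_exceeds_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.random(200)
        X = pd.DataFrame({"a": x, "b": x + 0.01 * rng.standard_normal(200)})
        out = val.vif(X)
        assert (out["vif"] > 10).all() and out["flag"].all()

    def test_requires_two_varying_predictors(self):
        with pytest.raises(ValueError):
            val.vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


def _ols_sim(rng, n=300, quad=0.0):
    x = rng.uniform(0, 2, n)
    y = 0.2 + 0.5 * x + quad * x**2 + 0.2 * rng.standard_normal(n)
    X = pd.DataFrame({"x": x, "const": 1.0})
    return est.fit_ols(X, y)


class TestMisspecificationTests:
    def test_reset_matches_statsmodels_reference(self):
        from statsmodels.stats.diagnostic import linear_reset

        rng = np.random.default_rng(5)
        res = _ols_sim(rng)
        ours = val.reset_test(res)
        ref = linear_reset(res._sm, power=[2, 3, 4], test_type="fitted",
                           use_f=True)
        assert ours["pvalue"] == pytest.approx(float(ref.pvalue), abs=1e-8)
        assert ours["statistic"] == pytest.approx(float(ref.statistic),
                                                  rel=1e-6)

    def test_reset_detects_omitted_quadratic(self):
        rng = np.random.default_rng(6)
        res = _ols_sim(rng, n=400, quad=0.4)
        assert val.reset_test(res)["verdict"] == "misspecified"

    def test_reset_size_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            val.reset_test(_ols_sim(rng, n=150))["pvalue"] < 0.05
            for _ in range(120))
        assert rejections / 120 < 0.13

    def test_reset_degrees_of_freedom_guard(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 5)
        res = est.fit_ols(pd.DataFrame({"x": x, "const": 1.0}),
                          0.5 * x + 0.01 * rng.standard_normal(5))
        with pytest.raises(ValueError):
            val.reset_test(res)

    def test_linktest_equals_power2_reset_for_ols(self):
        """On one dataset the OLS linktest p-value equals RESET restricted
        to the squared fitted value (same augmented regression)."""
        rng = np.random.default_rng(9)
        res = _ols_sim(rng, quad=0.2)
        lt = val.linktest(res)
        reset2 = val.reset_test(res, powers=(2,))
        assert lt["pvalue"] == pytest.approx(reset2["pvalue"], abs=1e-8)

    def test_linktest_flags_wrong_functional_form_for_tobit(self):
        rng = np.random.default_rng(10)
        n = 1500
        x = rng.uniform(0, 2, n)
        y = np.minimum(0.1 + 0.35 * x**2 + 0.2 * rng.standard_normal(n), 1.0)
        res = est.fit_tobit(pd.DataFrame({"x": x, "const": 1.0}), y)
        assert val.linktest(res)["verdict"] == "misspecified"

    def test_linktest_constant_predictor_rejected(self, frame):
        X = pd.DataFrame({"const": np.ones(len(frame))})
        res = est.fit_ols(X, frame["utility"])
        with pytest.raises(ValueError):
            val.linktest(res)


class TestSubgroups:
    def test_single_band_flags_undefined_anova(self):
        out = val.subgroup_summary([0.65] * 10, [0.6] * 10,
                                   bands=(0.6, 0.7, 0.8))
        assert np.isnan(out["anova"]["F"])
        assert "note" in out["anova"]

    def test_equal_group_means_give_near_zero_f(self):
        obs = np.r_[np.full(30, 0.2), np.full(30, 0.8)]
        pred = np.tile([0.4, 0.6], 30)
        out = val.subgroup_summary(obs, pred, bands=(0.0, 0.5, 1.0))
        assert out["anova"]["F"] == pytest.approx(0.0, abs=1e-10)

    def test_three_group_hand_anova(self):
        obs = np.r_[np.full(4, 0.1), np.full(4, 0.5), np.full(4, 0.9)]
        pred = np.array([0.1, 0.2, 0.1, 0.2, 0.5, 0.6, 0.5, 0.6,
                         0.8, 0.9, 0.8, 0.9])
        out = val.subgroup_summary(obs, pred, bands=(0.0, 0.3, 0.7, 1.0))
        groups = [pred[:4], pred[4:8], pred[8:]]
        grand = pred.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 9)
        assert out["anova"]["F"] == pytest.approx(f_hand)

    def test_fev1_severity_grouping(self, frame):
        out = val.subgroup_summary(frame["utility"], frame["utility"] * 0.9,
                                   groups=frame["fev1_severity"])
        assert set(out["table"].index) == {"mild", "moderate", "severe"}
        assert int(out["table"]["n"].sum()) == len(frame)


class TestCrossValidation:
    def test_folds_partition_with_balanced_sizes(self):
        ids = val.make_folds(401, 4, seed=0)
        sizes = np.bincount(ids)
        assert sizes.sum() == 401
        assert sizes.max() - sizes.min() <= 1

    def test_fold_assignment_is_seeded(self):
        a = val.make_folds(100, 4, seed=5)
        b = val.make_folds(100, 4, seed=5)
        c = val.make_folds(100, 4, seed=6)
        assert (a == b).all() and not (a == c).all()

    def test_noiseless_linear_model_has_zero_oof_error(self):
        from cfqrmap import cfqr

        rng = np.random.default_rng(11)
        n = 160
        data = pd.DataFrame({d: rng.uniform(0, 100, n)
                             for d in cfqr.MODELLING_DOMAINS})
        data["utility"] = (0.004 * data["physical"]
                          + 0.002 * data["role"] - 0.1)
        cv = val.cross_validate(data, 1, "ols", folds=4, seed=1)
        assert cv.fold_table["rmse"].max() < 1e-8
        counts = cv.folds.value_counts()
        assert counts.sum() == n and len(counts) == 4

    def test_oof_rmse_matches_noise_sd_for_the_true_model(self, frame):
        """For a correctly specified model the held-out RMSE estimates the
        noise SD."""
        from cfqrmap import cfqr

        rng = np.random.default_rng(12)
        n = 600
        data = pd.DataFrame({d: rng.uniform(0, 100, n)
                             for d in cfqr.MODELLING_DOMAINS})
        data["utility"] = (0.004 * data["physical"] + 0.3
                          + 0.12 * rng.standard_normal(n)).clip(None, 1.0)
        cv = val.cross_validate(data, 1, "ols", folds=4, seed=2)
        assert cv.fold_table["rmse"].mean() == pytest.approx(0.12, abs=0.02)

    def test_reproducible_under_seed(self, frame):
        cv1 = val.cross_validate(frame, 3, "ols", folds=4, seed=9)
        cv2 = val.cross_validate(frame, 3, "ols", folds=4, seed=9)
        pd.testing.assert_frame_equal(cv1.fold_table, cv2.fold_table)
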