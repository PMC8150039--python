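import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from speccurve import scales as scl
from speccurve.curve import (Specification, SpecificationCurve,
                             SpecificationCurveResults, SpecificationSpace,
                             build_default_space, fit_specification,
                             power_bivariate, summarize_curve)


class TestEnumeration:
    def test_default_space_is_972(self, scored424):
        space = build_default_space(scored424)
        assert len(space.outcomes) == 3
        assert len(space.predictors) == 9
        assert len(space.covariate_sets) == 18
        assert len(space.outlier_choices) == 2
        specs = space.enumerate()
        assert len(specs) == 972
        assert len(set(specs)) == 972

    def test_minimal_and_product_spaces(self):
        one = SpecificationSpace(["y"], ["x"], [()], ["include"])
        assert len(one.enumerate()) == 1
        four = SpecificationSpace(["y1", "y2"], ["x1", "x2"],
                                  [(), ("c",)], ["include", "exclude"])
        specs = four.enumerate()
        assert len(specs) == 16
        assert len(set(specs)) == 16

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            SpecificationSpace([], ["x"], [()])

    def test_item_level_space(self, scored424):
        space = build_default_space(scored424, item_level=True)
        assert len(space.predictors) == 15
        assert len(space.enumerate()) == 3 * 15 * 18 * 2

    def test_covariate_axis_names(self):
        covs = scl.covariate_names()
        assert len(covs) == 16
        assert {"age", "gender", "education", "weekly_game_time",
                "session_minutes"} <= set(covs)

    def test_predictor_in_covariates_rejected(self):
        with pytest.raises(ValueError):
            Specification("y", "x", ("x",), "include")


class TestFitSpecification:
    def test_bivariate_beta_equals_pearson_r(self, scored424):
        spec = Specification("life_satisfaction", "cvat2_11", (), "include")
        res = fit_specification(scored424, spec)
        r = np.corrcoef(scored424["cvat2_11"],
                        scored424["life_satisfaction"])[0, 1]
        assert abs(res.beta - r) < 1e-10
        assert abs(res.delta_r2 - res.beta ** 2) < 1e-10

    def test_outcome_identical_to_predictor(self, scored424):
        scored = scored424.copy()
        scored["mirror"] = scored["general_mental_health"]
        spec = Specification("general_mental_health", "mirror", (),
                             "include")
        res = fit_specification(scored, spec)
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.delta_r2 == pytest.approx(1.0, abs=1e-10)

    def test_against_statsmodels_oracle(self, scored424):
        """Coefficients, SEs, R2 and refit-difference Delta R2 match an
        independent statsmodels fit of the same standardized design."""
        spec = Specification("general_mental_health", "vat",
                             ("age", "gender", "pastime_motivation"),
                             "exclude")
        res = fit_specification(scored424, spec)
        sub = scored424.loc[~scored424["playtime_outlier"]]
        z = lambda x: (x - x.mean()) / x.std(ddof=1)
        X = pd.DataFrame({
            "vat": z(sub["vat"]), "age": z(sub["age"]),
            "gender_male": (sub["gender"] == "male").astype(float),
            "gender_other": (sub["gender"] == "other").astype(float),
            "pastime_motivation": z(sub["pastime_motivation"]),
        })
        y = z(sub["general_mental_health"])
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.beta == pytest.approx(fit.params["vat"], abs=1e-10)
        assert res.se == pytest.approx(fit.bse["vat"], abs=1e-10)
        assert res.r2 == pytest.approx(fit.rsquared, abs=1e-10)
        fit0 = sm.OLS(y, sm.add_constant(X.drop(columns="vat"))).fit()
        assert res.delta_r2 == pytest.approx(
            fit.rsquared - fit0.rsquared, abs=1e-10)
        # covariate rows: standardized for continuous, raw dummies for
        # categorical
        cov = {c[0]: c for c in res.covariate_stats}
        assert cov["age"][1] == pytest.approx(fit.params["age"], abs=1e-10)
        assert cov["gender"][1] == pytest.approx(
            fit.params["gender_male"], abs=1e-10)
        fit_ng = sm.OLS(y, sm.add_constant(
            X.drop(columns=["gender_male", "gender_other"]))).fit()
        assert cov["gender"][4] == pytest.approx(
            fit.rsquared - fit_ng.rsquared, abs=1e-10)

    def test_zero_variance_predictor_skipped(self, scored424):
        scored = scored424.copy()
        scored["flat"] = 2.0
        space = SpecificationSpace(["life_satisfaction"], ["flat", "vat"],
                                   [()], ["include"])
        res = SpecificationCurve(scored, space).fit()
        assert len(res) == 1
        assert len(res.skipped) == 1
        assert res.skipped[0][1].predictor == "flat"


class TestCurve:
    def test_full_run_counts_and_determinism(self, scored424,
                                             curve_results):
        assert len(curve_results) == 972
        again = SpecificationCurve(scored424,
                                   build_default_space(scored424)).fit()
        pd.testing.assert_frame_equal(curve_results.results, again.results)

    def test_sign_equivariance(self, scored424):
        flipped = scored424.copy()
        for o in scl.outcome_names():
            flipped[o] = -flipped[o]
        space = build_default_space(scored424)
        a = SpecificationCurve(scored424, space,
                               covariate_detail=False).fit().results
        b = SpecificationCurve(flipped, space,
                               covariate_detail=False).fit().results
        assert np.allclose(a["beta"], -b["beta"], atol=1e-10)
        assert np.allclose(a["pvalue"], b["pvalue"], atol=1e-10)
        assert np.allclose(a["r2"], b["r2"], atol=1e-10)
        assert np.allclose(a["delta_r2"], b["delta_r2"], atol=1e-10)

    def test_standardization_idempotence(self, scored424):
        spec = Specification("life_satisfaction", "gko",
                             ("age", "habit_motivation"), "include")
        res1 = fit_specification(scored424, spec)
        pre = scored424.copy()
        for col in ("life_satisfaction", "gko", "age", "habit_motivation"):
            x = pre[col].astype(float)
            pre[col] = (x - x.mean()) / x.std(ddof=1)
        res2 = fit_specification(pre, spec)
        assert res1.beta == pytest.approx(res2.beta, abs=1e-10)
        assert res1.se == pytest.approx(res2.se, abs=1e-10)

    def test_median_within_attained_range(self, curve_results):
        df = curve_results.results
        s = curve_results.summarize("all")
        assert s.min <= s.median <= s.max
        assert s.min == df["beta"].min()
        assert s.max == df["beta"].max()

    def test_item_level_betas_near_scale_level_hull(self, scored424):
        scale = SpecificationCurve(
            scored424, build_default_space(scored424),
            covariate_detail=False).fit().results
        items = SpecificationCurve(
            scored424, build_default_space(scored424, item_level=True),
            covariate_detail=False).fit().results
        lo, hi = scale["beta"].min(), scale["beta"].max()
        assert items["beta"].between(lo - 0.15, hi + 0.15).all()


class TestSummaries:
    @staticmethod
    def _fake_results(betas, ses, dr2=None):
        out = SpecificationCurveResults.__new__(SpecificationCurveResults)
        n = len(betas)
        out.results = pd.DataFrame({
            "spec_index": range(n), "outcome": ["y"] * n,
            "predictor": ["x"] * n, "covariates": ["none"] * n,
            "n_covariates": [0] * n, "outliers": ["include"] * n,
            "beta": betas, "se": ses,
            "ci_low": np.array(betas) - 2 * np.array(ses),
            "ci_high": np.array(betas) + 2 * np.array(ses),
            "pvalue": [0.01] * n, "df_resid": [100] * n,
            "r2": [0.2] * n,
            "delta_r2": dr2 if dr2 is not None else [0.1] * n,
            "n": [102] * n})
        out.covariate_results = pd.DataFrame(
            columns=["spec_index", "variable", "coef", "se", "df_resid",
                     "delta_r2", "standardized"])
        out.skipped = []
        return out

    def test_single_model(self):
        res = self._fake_results([-0.4], [0.05])
        s = summarize_curve(res, "all")
        assert s.median == -0.4
        from scipy import stats
        t = stats.t.ppf(0.975, 100)
        assert s.ci == pytest.approx((-0.4 - t * 0.05, -0.4 + t * 0.05))

    def test_odd_count_takes_central_model_ci(self):
        res = self._fake_results([-0.5, -0.1, -0.4], [0.01, 0.02, 0.05])
        s = summarize_curve(res, "all")
        assert s.median == -0.4
        from scipy import stats
        t = stats.t.ppf(0.975, 100)
        assert s.ci == pytest.approx((-0.4 - t * 0.05, -0.4 + t * 0.05))

    def test_even_count_averages_two_central(self):
        betas = [-0.6, -0.42, -0.38, -0.1]
        ses = [0.01, 0.03, 0.05, 0.07]
        s = summarize_curve(self._fake_results(betas, ses), "all")
        from scipy import stats
        t = stats.t.ppf(0.975, 100)
        b, se = -0.40, 0.04   # means of the two central estimates/SEs
        assert s.median == pytest.approx(b)
        assert s.ci == pytest.approx((b - t * se, b + t * se))

    def test_unknown_variable_rejected(self, curve_results):
        with pytest.raises(KeyError):
            summarize_curve(curve_results, "nonexistent")

    def test_covariate_summary_counts(self, curve_results):
        s = curve_results.summarize("age")
        # age appears in its singleton set and in the all-16 set:
        # 2 covariate sets x 3 outcomes x 9 predictors x 2 outlier rules
        assert s.n_models == 108
        g = curve_results.summarize("gender")
        assert g.n_models == 108


class TestPower:
    def test_study_power_statement(self):
        assert power_bivariate(424, 0.16) >= 0.90

    def test_null_beta_gives_alpha(self):
        assert power_bivariate(424, 0.0, alpha=0.05) == \
            pytest.approx(0.05, abs=1e-10)

    def test_monte_carlo_agreement(self):
        # vectorized simulation oracle for the bivariate t-test
        n, beta, reps = 424, 0.16, 20_000
        rng = np.random.default_rng(77)
        x = rng.standard_normal((n, reps))
        y = beta * x + np.sqrt(1 - beta ** 2) \
            * rng.standard_normal((n, reps))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        y = (y - y.mean(0)) / y.std(0, ddof=1)
        r = (x * y).sum(0) / (n - 1)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        from scipy import stats
        crit = stats.t.ppf(0.975, n - 2)
        mc = (np.abs(t) > crit).mean()
        assert abs(power_bivariate(n, beta) - mc) < 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            power_bivariate(3, 0.2)
        with pytest.raises(ValueError):
            power_bivariate(100, 1.2)
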