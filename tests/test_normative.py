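"""Normative layer: regressions, intervals, decade tables, ICC, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from datnorm import (
    Demographics,
    fit_normative_model,
    fit_simple_regression,
    generate_cohort,
    icc_between_conditions,
    predict_expected,
    prediction_interval,
    zscore_subject,
)
from datnorm.cohort import records_to_frame
from datnorm.errors import DegenerateModelError, DomainError, RankError, UndefinedIccError
from datnorm.normative import (
    anova_effects,
    decade_summary,
    format_p,
    paired_lr_ttest,
    percent_decline_per_decade,
)
from datnorm.published import AI_MODEL, SBR_MODEL


@pytest.fixture(scope="module")
def big_cohort():
    """n=5000 cohort at the published generative parameters."""
    return generate_cohort(5000, residual_sd=1.38, seed=123)


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        line = fit_simple_regression(x, 2 * x)
        assert line.slope == pytest.approx(2.0)
        assert line.r == pytest.approx(1.0)
        assert line.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 20)
        y = rng.normal(2 + 0.5 * x, 1.0)
        line = fit_simple_regression(x, y)
        # independent oracle: solve the normal equations directly
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert line.intercept == pytest.approx(beta[0], abs=1e-8)
        assert line.slope == pytest.approx(beta[1], abs=1e-8)
        # and statsmodels as a second, independent route
        import statsmodels.api as sm

        fit = sm.OLS(y, X).fit()
        assert line.residual_sd == pytest.approx(np.sqrt(fit.scale), abs=1e-8)
        assert abs(line.r) == pytest.approx(np.sqrt(fit.rsquared), abs=1e-8)

    def test_pooled_cohort_recovers_age_slope(self, big_cohort):
        """The pooled SBR-vs-age slope lands near the generative value."""
        df = records_to_frame(big_cohort)
        avg = 0.5 * (df["sbr_right"] + df["sbr_left"])
        line = fit_simple_regression(df["age"].to_numpy(), avg.to_numpy())
        # pooled slope mixes the age effect with sex/start-time composition;
        # compare against the generating age coefficient within 3 SE
        se = line.residual_sd / np.sqrt(line.sxx)
        assert abs(line.slope - SBR_MODEL.age) < 3 * se
        assert line.r < -0.4

    def test_constant_x_rejected(self):
        with pytest.raises(RankError):
            fit_simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNormativeModel:
    def test_noise_free_coefficients_recovered_exactly(self):
        records = generate_cohort(200, residual_sd=0.0, ai_residual_sd=0.0, seed=5)
        model = fit_normative_model(records, "average_sbr")
        for name, want in SBR_MODEL.as_dict().items():
            assert getattr(model.coefficients, name) == pytest.approx(want, abs=1e-9)
        assert model.residual_sd < 1e-9

    def test_noisy_coefficients_within_3_se(self, big_cohort):
        model = fit_normative_model(big_cohort, "average_sbr")
        for name, want in SBR_MODEL.as_dict().items():
            err = abs(getattr(model.coefficients, name) - want)
            assert err < 3 * model.coef_se[name], name

    def test_ai_noise_free_age_coefficient(self):
        records = generate_cohort(200, residual_sd=0.0, ai_residual_sd=0.0, seed=6)
        model = fit_normative_model(records, "ai")
        assert model.coefficients.age == pytest.approx(AI_MODEL.age, abs=1e-9)

    def test_single_sex_rejected(self):
        records = generate_cohort(
            20, seed=1, demographics=Demographics(female_fraction=0.0)
        )
        with pytest.raises(RankError):
            fit_normative_model(records, "average_sbr")


class TestPrediction:
    @pytest.fixture(scope="class")
    def model(self):
        return fit_normative_model(
            generate_cohort(200, residual_sd=0.0, ai_residual_sd=0.0, seed=5),
            "average_sbr",
        )

    def test_expected_value_male(self, model):
        # 10.610 - 0.063*57 + 0.263*3.5 = 7.9395
        assert predict_expected(model, 57, "M", 3.5) == pytest.approx(7.9395, abs=1e-6)

    def test_female_adds_sex_coefficient(self, model):
        male = predict_expected(model, 57, "M", 3.5)
        female = predict_expected(model, 57, "F", 3.5)
        assert female - male == pytest.approx(0.461, abs=1e-6)

    def test_age_linearity(self, model):
        a = predict_expected(model, 50, "M", 3.5)
        b = predict_expected(model, 60, "M", 3.5)
        assert b - a == pytest.approx(10 * model.coefficients.age, abs=1e-9)

    def test_degenerate_interval_when_noise_free(self, model):
        lo, hi = prediction_interval(model, (57, "M", 3.5), 0.95)
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_pi_contains_ci_everywhere(self, rng):
        x = rng.uniform(30, 83, 100)
        y = rng.normal(11.6 - 0.06 * x, 1.38)
        line = fit_simple_regression(x, y)
        for x0 in (30.0, 55.0, 83.0, 100.0):
            ci = line.confidence_interval(x0)
            pi = line.prediction_interval(x0)
            assert pi[0] < ci[0] < ci[1] < pi[1]

    def test_large_n_half_width_matches_residual_sd(self, big_cohort):
        """At n=5000 the 95% PI half-width approaches 1.96 * sigma ~ 2.70."""
        model = fit_normative_model(big_cohort, "average_sbr")
        lo, hi = prediction_interval(model, (56.5, "F", 3.5), 0.95)
        assert (hi - lo) / 2 == pytest.approx(2.70, abs=0.08)

    def test_invalid_level_rejected(self, model):
        with pytest.raises(DomainError):
            prediction_interval(model, (57, "M", 3.5), 1.5)


class TestDecadeSummary:
    def test_single_decade_cohort(self):
        records = generate_cohort(
            60, seed=2, demographics=Demographics(age_min=40.0, age_max=49.9)
        )
        table = decade_summary(records)
        both = table[table["group"] == "both"]
        populated = both[both["n_scans"] > 0]
        assert list(populated["decade"]) == ["40-49"]

    def test_noise_free_decade_means_linear(self):
        records = generate_cohort(
            600, residual_sd=0.0, ai_residual_sd=0.0, seed=8,
            demographics=Demographics(female_fraction=0.0, start_time_sd=0.0),
        )
        table = decade_summary(records, mode="predicted")
        men = table[(table["group"] == "men") & (table["n_scans"] > 0)]
        means = men["mean_sbr"].to_numpy()
        steps = np.diff(means)
        assert np.max(np.abs(steps - steps[0])) < 1e-9

    def test_percent_decline_per_decade(self, big_cohort):
        table = decade_summary(big_cohort, mode="predicted")
        both = table[table["group"] == "both"]
        decline = percent_decline_per_decade(both["mean_sbr"].to_numpy())
        assert decline == pytest.approx(6.3, abs=0.7)

    def test_lower_pi_below_mean(self, big_cohort):
        table = decade_summary(big_cohort)
        filled = table[table["n_scans"] > 0]
        assert (filled["sbr_lower_pi"] < filled["mean_sbr"]).all()


class TestIcc:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        res = icc_between_conditions(np.column_stack([x, x]))
        assert res.estimate == pytest.approx(1.0)

    def test_offset_penalized_vs_pearson(self, rng):
        x = rng.normal(8.0, 1.5, 100)
        pairs = np.column_stack([x, x + 4.0])
        res = icc_between_conditions(pairs)
        assert res.estimate < 0.5  # Pearson r would be 1.0

    def test_independent_pairs_near_zero(self, rng):
        pairs = rng.standard_normal((500, 2))
        res = icc_between_conditions(pairs)
        assert abs(res.estimate) < 0.1
        assert res.ci_lower <= res.estimate <= res.ci_upper

    def test_swap_invariance(self, rng):
        pairs = rng.normal(8.0, 2.0, (50, 2))
        a = icc_between_conditions(pairs)
        b = icc_between_conditions(pairs[:, ::-1])
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_matches_pingouin(self, rng):
        """Cross-check ICC(2,1) and its CI against an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(8.0, 1.5, 60)
        pairs = np.column_stack([x + rng.normal(0, 0.5, 60), 1.1 * x + rng.normal(0, 0.5, 60)])
        ours = icc_between_conditions(pairs)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(60), 2),
                "rater": np.tile(["a", "b"], 60),
                "score": pairs.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert ours.estimate == pytest.approx(row["ICC"], abs=1e-6)
        # pingouin rounds the CI to 2 decimals
        assert ours.ci_lower == pytest.approx(row["CI95"][0], abs=0.02)
        assert ours.ci_upper == pytest.approx(row["CI95"][1], abs=0.02)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedIccError):
            icc_between_conditions(np.full((5, 2), 3.0))


class TestAnova:
    def test_f_nonnegative_and_effects_present(self, big_cohort):
        table = anova_effects(big_cohort, "average_sbr")
        assert set(table["effect"]) == {"sex", "age", "sex_x_age", "start_time"}
        assert (table["F"] >= 0).all()
        age_p = table.set_index("effect").loc["age", "p_value"]
        assert age_p < 1e-6  # strong generative age effect

    def test_type_i_error_under_null(self):
        """With no generative effects each test rejects at ~5%."""
        null = {"intercept": 8.0, "age": 0.0, "start_time": 0.0, "sex_female": 0.0}
        from datnorm.normative import LinearCoefficients

        coeffs = LinearCoefficients(**null)
        ai = LinearCoefficients(4.0, 0.0, 0.0, 0.0)
        n_reps, n = 400, 150
        rejections = {e: 0 for e in ("sex", "age", "sex_x_age", "start_time")}
        for rep in range(n_reps):
            records = generate_cohort(
                n, coefficients=coeffs, residual_sd=1.0,
                ai_coefficients=ai, ai_residual_sd=1.0, seed=10_000 + rep,
            )
            table = anova_effects(records, "average_sbr").set_index("effect")
            for effect in rejections:
                if table.loc[effect, "p_value"] < 0.05:
                    rejections[effect] += 1
        for effect, count in rejections.items():
            rate = count / n_reps
            assert 0.025 <= rate <= 0.075, f"{effect}: {rate}"

    def test_interaction_power(self):
        """A strong built-in sex x age interaction is detected reliably."""
        from datnorm.normative import LinearCoefficients

        base = LinearCoefficients(10.0, -0.06, 0.0, 0.0)
        ai = LinearCoefficients(4.0, 0.0, 0.0, 0.0)
        detected = 0
        n_reps = 60
        for rep in range(n_reps):
            records = generate_cohort(
                300, coefficients=base, residual_sd=1.0,
                ai_coefficients=ai, ai_residual_sd=1.0, seed=20_000 + rep,
            )
            df = records_to_frame(records)
            female = (df["sex"] == "F").to_numpy(float)
            interaction = 0.05 * female * df["age"].to_numpy()
            df["sbr_right"] = df["sbr_right"] + interaction
            df["sbr_left"] = df["sbr_left"] + interaction
            table = anova_effects(df, "average_sbr").set_index("effect")
            if table.loc["sex_x_age", "p_value"] < 0.05:
                detected += 1
        assert detected / n_reps >= 0.95

    def test_p_floor_formatting(self):
        assert format_p(0.0) == "< 1e-15"
        assert format_p(0.04) == "0.04"


class TestZScore:
    @pytest.fixture(scope="class")
    def model(self):
        return fit_normative_model(generate_cohort(2000, seed=11), "average_sbr")

    def _record(self, observed, age=60.0):
        return pd.DataFrame(
            [
                {
                    "subject_id": "q", "age": age, "sex": "M",
                    "scan_start_time": 3.5, "sbr_right": observed,
                    "sbr_left": observed, "sbr_calibrated_right": None,
                    "sbr_calibrated_left": None,
                }
            ]
        )

    def test_observed_equals_expected(self, model):
        expected = predict_expected(model, 60.0, "M", 3.5)
        res = zscore_subject(model, self._record(expected))
        assert res.z == pytest.approx(0.0, abs=1e-9)
        assert not res.below_lower_pi

    def test_just_below_lower_pi_flagged(self, model):
        lo, _ = prediction_interval(model, (60.0, "M", 3.5), 0.95)
        res = zscore_subject(model, self._record(lo - 1e-6))
        assert res.below_lower_pi
        res2 = zscore_subject(model, self._record(lo + 1e-3))
        assert not res2.below_lower_pi

    def test_degenerate_model_rejected(self):
        model = fit_normative_model(
            generate_cohort(100, residual_sd=0.0, ai_residual_sd=0.0, seed=12),
            "average_sbr",
        )
        with pytest.raises(DegenerateModelError):
            zscore_subject(model, self._record(5.0))


class TestPairedAsymmetry:
    def test_right_dominance_detected(self, big_cohort):
        res = paired_lr_ttest(big_cohort)
        assert res.statistic > 0  # right > left on average by construction
        assert res.pvalue < 0.001
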