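"""Survey-side models: parameter recovery, Brant's test, profile predictions."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mdesim.hazards import AttributeProfile, enumerate_profiles
from mdesim.observe import WEEKS_CATEGORIES
from mdesim.regression import (
    BinaryModelFit,
    BrantUntestableError,
    OrdinalModelFit,
    SeparationError,
    brant_test,
    fit_binary_logistic,
    fit_discrete_time_cloglog,
    fit_ordinal_logistic,
    fitted_profile_probabilities,
)
from mdesim.synth import (
    PUBLISHED_BINARY_LOG_ORS,
    PUBLISHED_ORDINAL_COEFFS,
    PopulationSpec,
    category_probabilities,
    generate_survey,
)


class TestBinaryLogistic:
    def test_recovers_published_stressor_odds_ratio(self, big_survey):
        fit = fit_binary_logistic(big_survey)
        assert fit.converged
        assert fit.odds_ratios["childhood_stressor"] == pytest.approx(2.0, abs=0.15)
        lo, hi = fit.conf_int["childhood_stressor"]
        assert lo < fit.odds_ratios["childhood_stressor"] < hi

    def test_null_generator_gives_unit_odds_ratios(self):
        spec = PopulationSpec(
            n_respondents=20_000,
            binary_intercept=-1.0,
            binary_log_odds_ratios={k: 0.0 for k in PUBLISHED_BINARY_LOG_ORS},
            seed=3,
        )
        fit = fit_binary_logistic(generate_survey(spec))
        for t, orr in fit.odds_ratios.items():
            assert orr == pytest.approx(1.0, abs=0.15), t

    def test_perfect_separation_raises(self):
        df = pd.DataFrame(
            {
                "age_group": ["12-18"] * 10 + ["26-45"] * 10,
                "pain": [0] * 20,
                "smoker": [0] * 20,
                "childhood_stressor": [0] * 10 + [1] * 10,
                "followup_positive": [0] * 10 + [1] * 10,
            }
        )
        with pytest.raises(SeparationError):
            fit_binary_logistic(df)

    def test_single_class_outcome_rejected(self):
        df = generate_survey(PopulationSpec(n_respondents=50, seed=1))
        df["followup_positive"] = 0
        with pytest.raises(ValueError):
            fit_binary_logistic(df)

    def test_bias_shrinks_with_sample_size(self, big_survey):
        truth = PUBLISHED_BINARY_LOG_ORS["childhood_stressor"]
        err_large = abs(
            np.log(fit_binary_logistic(big_survey).odds_ratios["childhood_stressor"]) - truth
        )
        small_errs = []
        for s in range(4):
            df = generate_survey(PopulationSpec(n_respondents=1_500, seed=100 + s))
            small_errs.append(
                abs(np.log(fit_binary_logistic(df).odds_ratios["childhood_stressor"]) - truth)
            )
        assert err_large < np.mean(small_errs)


class TestOrdinalLogistic:
    def test_recovers_published_age_coefficient(self, big_survey):
        fit = fit_ordinal_logistic(big_survey)
        assert fit.converged
        assert fit.coefficients["age_46_65"] == pytest.approx(0.441, abs=0.1)
        # cut points recovered and increasing
        assert list(fit.cut_points) == sorted(fit.cut_points)
        assert np.allclose(fit.cut_points, (0.0, 0.8, 1.6), atol=0.12)

    def test_null_generator_gives_zero_coefficients(self):
        spec = PopulationSpec(
            n_respondents=20_000,
            ordinal_coefficients={k: 0.0 for k in PUBLISHED_ORDINAL_COEFFS},
            seed=4,
        )
        fit = fit_ordinal_logistic(generate_survey(spec))
        for t, c in fit.coefficients.items():
            assert c == pytest.approx(0.0, abs=0.15), t

    def test_predicted_distribution_normalised(self, big_survey):
        fit = fit_ordinal_logistic(big_survey)
        for profile in enumerate_profiles()[:8]:
            dist = fit.predict_category_distribution(profile)
            assert dist.shape == (4,)
            assert dist.min() > 0
            assert dist.sum() == pytest.approx(1.0)

    def test_single_category_rejected(self):
        df = generate_survey(PopulationSpec(n_respondents=100, seed=5))
        df["weeks_category"] = "1-6"
        with pytest.raises(ValueError):
            fit_ordinal_logistic(df)


class TestBrant:
    def test_df_convention(self, big_survey):
        res = brant_test(big_survey)
        # J=4 categories, K=4 covariates -> (J-2)*K = 8
        assert res.df == 8
        assert res.chi_square >= 0
        assert 0 <= res.p_value <= 1
        assert len(res.per_variable) == 4
        assert (res.per_variable["df"] == 2).all()

    def test_invariant_to_covariate_relabeling(self, big_survey):
        a = brant_test(big_survey, terms=("age_19_25", "age_26_45", "age_46_65", "age_66_plus"))
        b = brant_test(big_survey, terms=("age_66_plus", "age_46_65", "age_26_45", "age_19_25"))
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-8)
        assert a.df == b.df

    def test_nonproportional_slopes_detected(self):
        # Binary covariate whose effect reverses across cumulative splits:
        # strongly non-parallel, must be rejected at n = 5000.
        rng = np.random.default_rng(11)
        n = 5_000
        x = rng.random(n) < 0.5
        probs0 = np.array([0.40, 0.20, 0.20, 0.20])
        probs1 = np.array([0.20, 0.40, 0.30, 0.10])
        cats = np.array(WEEKS_CATEGORIES, dtype=object)
        idx = np.empty(n, dtype=int)
        for val, probs in ((False, probs0), (True, probs1)):
            m = x == val
            idx[m] = rng.choice(4, size=m.sum(), p=probs)
        df = pd.DataFrame(
            {
                "age_group": "12-18",
                "pain": x.astype(int),
                "smoker": 0,
                "childhood_stressor": 0,
                "weeks_category": cats[idx],
            }
        )
        res = brant_test(df, terms=("pain",))
        assert res.df == 2
        assert res.p_value < 0.001

    def test_empty_cumulative_split_untestable(self):
        df = generate_survey(PopulationSpec(n_respondents=200, seed=6))
        df.loc[df["weeks_category"] == "26-52", "weeks_category"] = "13-25"
        with pytest.raises(BrantUntestableError):
            brant_test(df)


@pytest.fixture(scope="module")
def truth_fits():
    binary = BinaryModelFit(
        terms=tuple(PUBLISHED_BINARY_LOG_ORS),
        intercept=-2.0,
        coefficients=dict(PUBLISHED_BINARY_LOG_ORS),
        standard_errors={k: 0.0 for k in PUBLISHED_BINARY_LOG_ORS},
        odds_ratios={k: float(np.exp(v)) for k, v in PUBLISHED_BINARY_LOG_ORS.items()},
        conf_int={k: (0.0, np.inf) for k in PUBLISHED_BINARY_LOG_ORS},
        converged=True,
    )
    ordinal = OrdinalModelFit(
        terms=tuple(PUBLISHED_ORDINAL_COEFFS),
        coefficients=dict(PUBLISHED_ORDINAL_COEFFS),
        cut_points=(0.0, 0.8, 1.6),
        standard_errors={k: 0.0 for k in PUBLISHED_ORDINAL_COEFFS},
        converged=True,
    )
    return binary, ordinal


class TestProfilePredictions:
    def test_table_shape(self, truth_fits):
        table = fitted_profile_probabilities(*truth_fits, enumerate_profiles())
        assert len(table) == 40
        prob_cols = ["p_followup_positive"] + [f"p_weeks_{c}" for c in WEEKS_CATEGORIES]
        assert all(c in table.columns for c in prob_cols)

    def test_ordinal_prediction_depends_only_on_age(self, truth_fits):
        table = fitted_profile_probabilities(*truth_fits, enumerate_profiles())
        cols = [f"p_weeks_{c}" for c in WEEKS_CATEGORIES]
        for _, grp in table.groupby("age_group"):
            assert (grp[cols].nunique() == 1).all()

    def test_reference_profile_is_inverse_logit_of_intercept(self, truth_fits):
        binary, _ = truth_fits
        assert binary.predict_probability(AttributeProfile("12-18")) == pytest.approx(
            float(expit(-2.0))
        )

    def test_predictions_reproduce_generator_cells_exactly(self, truth_fits):
        # Composing the fitted-value machinery with the generating truth
        # must give the generator's closed-form cell probabilities.
        binary, ordinal = truth_fits
        profiles = enumerate_profiles()
        cov = pd.DataFrame(
            {
                "age_group": [p.age_group for p in profiles],
                "pain": [int(p.pain) for p in profiles],
                "smoker": [int(p.smoker) for p in profiles],
                "childhood_stressor": [int(p.childhood_stressor) for p in profiles],
            }
        )
        gen = category_probabilities(cov, (0.0, 0.8, 1.6), dict(PUBLISHED_ORDINAL_COEFFS))
        for i, p in enumerate(profiles):
            assert np.allclose(ordinal.predict_category_distribution(p), gen[i], atol=1e-12)


class TestDiscreteTimeCloglog:
    def test_recovers_generating_hazard(self, recovery_params):
        from mdesim.simulate import simulate_durations

        rng = np.random.default_rng(21)
        d, e = simulate_durations(AttributeProfile("12-18"), 8_000, recovery_params, rng=rng)
        fit = fit_discrete_time_cloglog(d, e, pd.DataFrame(index=range(8_000)))
        assert fit.params["const"] == pytest.approx(recovery_params.alpha, abs=0.1)
        assert fit.params["log_week"] == pytest.approx(recovery_params.log_time, abs=0.1)
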