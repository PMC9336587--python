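import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from brainthermo import (
    BRAIN_TEMP_SPEC,
    OUTCOME_SPEC,
    GeneratorConfig,
    assemble_model_table,
    fit_outcome_model,
    fit_temperature_model,
    gen_cohort_outcomes,
    gen_mrs_dataset,
    odds_transform,
    power_simulation,
    shift_to_temperature,
)
from brainthermo.synthdata import CohortParams


def newton_raphson_logit(X, y, tol=1e-12, max_iter=200):
    """Independent brute-force ML logit oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X.T * W) @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestAssembleTable:
    def test_incomplete_rows_dropped(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "died": [0, 1, 0],
             "age": [40.0, np.nan, 60.0], "sex": ["male"] * 3,
             "brain_mean_c": [38.0, 38.5, 39.0],
             "brain_range_c": [3.0, 2.5, 3.5], "daily_rhythm": [1, 0, 1]}
        )
        out, n = assemble_model_table(df, OUTCOME_SPEC)
        assert n == 2
        # retained rows unaltered
        assert out.loc[out.subject_id == "a", "age"].iloc[0] == 40.0

    def test_complete_table_passthrough(self):
        df, _ = gen_cohort_outcomes(GeneratorConfig(seed=1))
        out, n = assemble_model_table(df, OUTCOME_SPEC)
        assert n == len(df)

    def test_missing_term_raises(self):
        with pytest.raises(KeyError):
            assemble_model_table(pd.DataFrame({"died": [0, 1]}), OUTCOME_SPEC)


class TestOutcomeModel:
    def test_matches_newton_raphson_oracle_on_small_table(self):
        from brainthermo import ModelSpec

        rng = np.random.default_rng(12)
        n = 10
        # compact spec: with 10 rows the full five-term model is on the edge
        # of separation, which is not what this equivalence check is about
        spec = ModelSpec(
            response="died",
            fixed_effects={"age": "continuous", "daily_rhythm": "continuous"},
            family="binomial",
        )
        df = pd.DataFrame(
            {"subject_id": [f"p{i}" for i in range(n)],
             "age": rng.uniform(20, 80, n),
             "daily_rhythm": [0, 1] * 5,
             "died": [0, 1, 1, 0, 0, 1, 1, 0, 0, 1]}
        )
        res = fit_outcome_model(df, spec)
        from patsy import dmatrices
        _, X = dmatrices(spec.formula(), df, return_type="dataframe")
        beta = newton_raphson_logit(X.to_numpy(), df["died"].to_numpy(float))
        assert not res.penalized
        assert np.allclose(res.table["estimate"].to_numpy(), beta, atol=1e-8)

    def test_null_generator_ors_cover_one(self):
        cfg = GeneratorConfig(
            seed=3,
            cohort=CohortParams(or_rhythm=1.0, or_age_per_yr=1.0, or_mean_per_c=1.0,
                                baseline_death_rate=0.25),
        )
        df, _ = gen_cohort_outcomes(cfg)
        res = fit_outcome_model(df)
        for term in ("daily_rhythm", "age", "brain_mean_c"):
            row = res.term(term)
            assert row.or_low <= 1.0 <= row.or_high

    def test_death_coded_one(self):
        """A protective rhythm effect must come out with OR < 1."""
        df, truth = gen_cohort_outcomes(GeneratorConfig(seed=4))
        res = fit_outcome_model(df)
        assert res.term("daily_rhythm").or_ < 1.0
        assert res.term("age").or_ > 1.0

    def test_non_binary_outcome_rejected(self):
        df, _ = gen_cohort_outcomes(GeneratorConfig(seed=5))
        df["died"] = df["died"].astype(float) + 0.5
        with pytest.raises(ValueError):
            fit_outcome_model(df)

    def test_separation_falls_back_penalized(self):
        df = pd.DataFrame(
            {"subject_id": [f"p{i}" for i in range(12)],
             "age": np.r_[np.full(6, 30.0), np.full(6, 70.0)],
             "sex": ["male"] * 12,
             "brain_mean_c": np.full(12, 38.5),
             "brain_range_c": np.full(12, 3.0),
             "daily_rhythm": [1] * 6 + [0] * 6,
             "died": [0] * 6 + [1] * 6}  # rhythm separates outcome perfectly
        )
        res = fit_outcome_model(df)
        assert res.penalized
        assert np.all(np.isfinite(res.table["estimate"]))

    def test_rescaling_predictor_rescales_estimate(self):
        df, _ = gen_cohort_outcomes(GeneratorConfig(seed=6))
        res1 = fit_outcome_model(df)
        df2 = df.copy()
        df2["age"] = df2["age"] / 10.0
        res2 = fit_outcome_model(df2)
        assert res2.term("age").estimate == pytest.approx(
            10 * res1.term("age").estimate, rel=1e-6
        )

    def test_per_decade_or_identity(self):
        df, _ = gen_cohort_outcomes(GeneratorConfig(seed=7))
        res = fit_outcome_model(df)
        or_yr = res.term("age").or_
        or_decade = np.exp(res.term("age").estimate * 10)
        assert or_decade == pytest.approx(or_yr**10, rel=1e-9)


class TestOddsTransform:
    def test_zero_is_or_one(self):
        or_, (lo, hi) = odds_transform(0.0, (-1.0, 1.0))
        assert or_ == 1.0
        assert (lo, hi) == pytest.approx((np.exp(-1), np.exp(1)))

    def test_per_decade_transform(self):
        or_, _ = odds_transform(np.log(1.10) * 10, (0.0, 0.0))
        assert or_ == pytest.approx(1.10**10, rel=1e-9)


class TestTemperatureModel:
    def test_near_zero_noise_recovers_exactly(self):
        from brainthermo.synthdata import MRSParams
        cfg = GeneratorConfig(
            seed=8,
            mrs=MRSParams(n_subjects=12, n_female=6, n_luteal=4,
                          residual_sd=1e-3, subject_intercept_sd=0.0,
                          subject_slope_sd=0.0, n_qc_violations=0,
                          # a single common age slope: the global model has one
                          # Age term, so exact recovery needs a homogeneous slope
                          deep_age_slope=0.01, sup_age_slope=0.01),
        )
        df, truth = gen_mrs_dataset(cfg)
        df["brain_temp_c"], _ = shift_to_temperature(
            df["naa_ppm"].to_numpy(), df["water_ppm"].to_numpy()
        )
        res = fit_temperature_model(df, BRAIN_TEMP_SPEC)
        assert res.term("[T.male]").estimate == pytest.approx(-truth["sex_effect"], abs=1e-3)
        assert res.term("time_norm").estimate == pytest.approx(truth["time_effect"], abs=1e-3)
        assert res.term("[T.Thalamus]").estimate == pytest.approx(
            truth["region_offsets"]["Thalamus"], abs=1e-3
        )

    def test_planted_effects_within_ci(self):
        df, truth = gen_mrs_dataset(GeneratorConfig(seed=9))
        df["brain_temp_c"], _ = shift_to_temperature(
            df["naa_ppm"].to_numpy(), df["water_ppm"].to_numpy()
        )
        res = fit_temperature_model(df, BRAIN_TEMP_SPEC)
        row = res.term("[T.male]")
        assert row.ci_low <= -truth["sex_effect"] <= row.ci_high
        row = res.term("time_norm")
        assert row.ci_low <= truth["time_effect"] <= row.ci_high
        deep = fit_temperature_model(df, BRAIN_TEMP_SPEC, deep_only=True)
        row = deep.term("age")
        assert row.ci_low <= truth["deep_age_slope"] <= row.ci_high
        assert deep.n_used == 40 * 3 * 2

    def test_single_observation_drops_random_slope(self):
        df, _ = gen_mrs_dataset(GeneratorConfig(seed=10))
        df["brain_temp_c"], _ = shift_to_temperature(
            df["naa_ppm"].to_numpy(), df["water_ppm"].to_numpy()
        )
        one_session = df[df["session_clock_time"] == 9.5]
        res = fit_temperature_model(one_session, BRAIN_TEMP_SPEC)
        assert any("random slope dropped" in n for n in res.notes)


class TestPowerSimulation:
    def test_null_power_near_alpha(self):
        res = power_simulation(true_diff=0.0, n_reps=400, seed=1)
        assert abs(res["power"] - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400) + 0.01

    def test_huge_effect_power_one(self):
        res = power_simulation(true_diff=5.0, sd_within=0.1, n_reps=200, seed=2)
        assert res["power"] == 1.0

    def test_default_design_reports_power_with_ci(self):
        res = power_simulation(n_reps=200, seed=3)
        assert 0.0 <= res["ci_low"] <= res["power"] <= res["ci_high"] <= 1.0

    def test_low_reps_warns(self):
        with pytest.warns(UserWarning):
            power_simulation(n_reps=50, seed=4)
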