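import math
from dataclasses import replace

import numpy as np
import pytest

from strokerisk.errors import ConfigError, CovariateError, ProfileError, ScoringError
from strokerisk.risk_models import (
    BmiRule,
    CoefficientSet,
    RiskFactorProfile,
    RiskometerDeltaConfig,
    anthropometric_delta,
    baseline_reference_risk,
    default_model_config,
    fsrs_risk,
    linear_predictor,
    reference_profile,
    risk_from_lp,
    riskometer_lp_delta,
    riskometer_risk,
    score_cohort,
)

from conftest import random_profile


class TestProfileValidation:
    def test_valid_profile(self):
        RiskFactorProfile(age=45, sex="female", sbp=120)

    @pytest.mark.parametrize("kwargs", [
        {"age": 15},
        {"sex": "other"},
        {"sbp": -10},
        {"smoking": "sometimes"},
        {"whr": 0.0},
        {"bmi": -1.0},
        {"waist_circumference_cm": 0.0},
        {"ethnic_group": "martian"},
    ])
    def test_invalid_fields(self, kwargs):
        base = dict(age=45, sex="female", sbp=120)
        base.update(kwargs)
        with pytest.raises(ProfileError):
            RiskFactorProfile(**base)

    def test_cognitive_and_memory_mutually_exclusive(self):
        with pytest.raises(ProfileError, match="memory"):
            RiskFactorProfile(age=45, sex="male", sbp=120,
                              cognitive_problems=True, memory_problems=True)


class TestCoefficientSet:
    def test_s0_out_of_range_rejected(self):
        with pytest.raises(ConfigError, match="baseline survival"):
            CoefficientSet(sex="male", betas={}, covariate_means={},
                           baseline_survival={10: 1.5})

    def test_s0_ordering_enforced(self):
        with pytest.raises(ConfigError, match="S0"):
            CoefficientSet(sex="male", betas={}, covariate_means={},
                           baseline_survival={5: 0.90, 10: 0.95})

    def test_s5_derived_from_s10_constant_hazard(self):
        coeffs = CoefficientSet(sex="male", betas={}, covariate_means={},
                                baseline_survival={10: 0.81})
        assert coeffs.baseline_survival_at(5) == pytest.approx(0.9, rel=1e-12)

    def test_explicit_s5_takes_precedence(self):
        coeffs = CoefficientSet(sex="male", betas={}, covariate_means={},
                                baseline_survival={5: 0.95, 10: 0.81})
        assert coeffs.baseline_survival_at(5) == 0.95

    def test_missing_horizon_errors(self):
        coeffs = CoefficientSet(sex="male", betas={}, covariate_means={},
                                baseline_survival={5: 0.95})
        with pytest.raises(ConfigError, match="horizon"):
            coeffs.baseline_survival_at(10)


class TestLinearPredictor:
    def test_all_covariates_zero_gives_zero(self):
        # no covariates referenced -> empty sum
        coeffs = CoefficientSet(sex="male", betas={}, covariate_means={},
                                baseline_survival={10: 0.9})
        profile = RiskFactorProfile(age=60, sex="male", sbp=140)
        assert linear_predictor(profile, coeffs) == 0.0

    def test_single_indicator_returns_its_beta(self):
        coeffs = CoefficientSet(sex="male", betas={"diabetes": 0.42},
                                covariate_means={}, baseline_survival={10: 0.9})
        profile = RiskFactorProfile(age=60, sex="male", sbp=140, diabetes=True)
        assert linear_predictor(profile, coeffs) == 0.42

    def test_five_covariate_dot_product(self, toy_coeffs_male):
        # hand-computed: 0.05*60 + 0.01*150 + 0.3 + 0.5 + 0.6 = 5.9
        profile = RiskFactorProfile(age=60, sex="male", sbp=150, diabetes=True,
                                    smoking="current", atrial_fibrillation=True)
        assert linear_predictor(profile, toy_coeffs_male) == pytest.approx(5.9, rel=1e-12)

    def test_sex_mismatch_errors(self, toy_coeffs_male):
        profile = RiskFactorProfile(age=60, sex="female", sbp=140)
        with pytest.raises(ConfigError, match="sex"):
            linear_predictor(profile, toy_coeffs_male)

    def test_unknown_covariate_named_in_error(self):
        coeffs = CoefficientSet(sex="male", betas={"cholesterol": 0.1},
                                covariate_means={}, baseline_survival={10: 0.9})
        profile = RiskFactorProfile(age=60, sex="male", sbp=140)
        with pytest.raises(CovariateError, match="cholesterol"):
            linear_predictor(profile, coeffs)

    def test_ex_smoker_maps_to_zero_without_ex_beta(self, toy_coeffs_male):
        never = RiskFactorProfile(age=60, sex="male", sbp=140, smoking="never")
        ex = RiskFactorProfile(age=60, sex="male", sbp=140, smoking="ex")
        assert linear_predictor(never, toy_coeffs_male) == \
            linear_predictor(ex, toy_coeffs_male)


class TestRiskFromLp:
    def test_exponent_collapses_at_covariate_means(self):
        coeffs = CoefficientSet(
            sex="male", betas={"age": 0.05, "sbp": 0.01},
            covariate_means={"age": 60.0, "sbp": 140.0},
            baseline_survival={10: 0.88},
        )
        lp_at_means = 0.05 * 60 + 0.01 * 140
        assert risk_from_lp(lp_at_means, coeffs, 10) == pytest.approx(1 - 0.88, rel=1e-12)

    def test_s0_of_one_gives_zero_risk(self):
        coeffs = CoefficientSet(sex="male", betas={}, covariate_means={},
                                baseline_survival={10: 1.0})
        for lp in (-5.0, 0.0, 7.0):
            assert risk_from_lp(lp, coeffs, 10) == 0.0

    def test_closed_form_hand_value(self, toy_coeffs_male):
        # S0(10)=0.9, centered lp = ln 2 -> 1 - 0.9^2 = 0.19
        assert risk_from_lp(math.log(2), toy_coeffs_male, 10) == pytest.approx(0.19, rel=1e-12)

    def test_extreme_lp_clips_to_one(self, toy_coeffs_male):
        assert risk_from_lp(1e4, toy_coeffs_male, 10) == pytest.approx(1.0)


class TestFsrsRisk:
    def test_reference_profile_equals_baseline(self, toy_coeffs_male):
        ref = reference_profile(70, "male", toy_coeffs_male)
        est = fsrs_risk(ref, toy_coeffs_male, 10)
        assert est.absolute_risk_percent == pytest.approx(est.baseline_risk_percent, rel=1e-12)
        assert est.model == "fsrs"

    def test_risk_increases_with_sbp(self, toy_coeffs_male):
        risks = [
            fsrs_risk(RiskFactorProfile(age=60, sex="male", sbp=s), toy_coeffs_male, 10)
            .absolute_risk_percent
            for s in (120, 140, 160, 180)
        ]
        assert all(a < b for a, b in zip(risks, risks[1:]))

    def test_end_to_end_closed_form(self, toy_coeffs_male):
        profile = RiskFactorProfile(age=55, sex="male", sbp=135, diabetes=True)
        lp = 0.05 * 55 + 0.01 * 135 + 0.3
        expected = 100 * (1 - 0.90 ** math.exp(lp))
        est = fsrs_risk(profile, toy_coeffs_male, 10)
        assert est.absolute_risk_percent == pytest.approx(expected, rel=1e-12)
        assert est.linear_predictor == pytest.approx(lp, rel=1e-12)

    def test_bad_horizon_rejected(self, toy_coeffs_male, base_profile):
        with pytest.raises(ConfigError, match="horizon"):
            fsrs_risk(base_profile, toy_coeffs_male, 7)


class TestAnthropometricDelta:
    def test_whr_at_threshold_is_zero(self, deltas):
        p = RiskFactorProfile(age=60, sex="male", sbp=140, whr=0.96)
        assert anthropometric_delta(p, deltas) == 0.0

    def test_whr_printed_rule(self, deltas):
        # male whr 0.98: 0.20 + 0.10 * 2 units of 0.01 = 0.40
        p = RiskFactorProfile(age=60, sex="male", sbp=140, whr=0.98)
        assert anthropometric_delta(p, deltas) == pytest.approx(0.40, rel=1e-12)

    def test_whr_female_threshold(self, deltas):
        p = RiskFactorProfile(age=60, sex="female", sbp=140, whr=0.80)
        assert anthropometric_delta(p, deltas) == 0.0
        p2 = RiskFactorProfile(age=60, sex="female", sbp=140, whr=0.81)
        assert anthropometric_delta(p2, deltas) == pytest.approx(0.30, rel=1e-9)

    def test_waist_printed_rule(self, deltas):
        # female waist 90 cm: 1 cm above 89 -> ln(1.02)
        p = RiskFactorProfile(age=60, sex="female", sbp=140, waist_circumference_cm=90)
        assert anthropometric_delta(p, deltas) == pytest.approx(math.log(1.02), rel=1e-12)

    def test_bmi_rule_per_ethnic_thresholds(self, deltas):
        for ethnic, threshold in (("chinese", 24), ("south_asian", 23), ("other", 25)):
            p = RiskFactorProfile(age=60, sex="male", sbp=140, bmi=threshold + 2,
                                  ethnic_group=ethnic)
            assert anthropometric_delta(p, deltas) == pytest.approx(0.20, rel=1e-9)
            at = RiskFactorProfile(age=60, sex="male", sbp=140, bmi=float(threshold),
                                   ethnic_group=ethnic)
            assert anthropometric_delta(at, deltas) == 0.0

    def test_bmi_optional_base_term(self):
        config = RiskometerDeltaConfig(bmi_rule=BmiRule(include_base_term=True))
        p = RiskFactorProfile(age=60, sex="male", sbp=140, bmi=27)
        assert anthropometric_delta(p, config) == pytest.approx(0.2 + math.log(1.02), rel=1e-9)

    def test_fallback_precedence_whr_wins(self, deltas):
        with_all = RiskFactorProfile(age=60, sex="male", sbp=140, whr=0.98,
                                     bmi=40, waist_circumference_cm=150)
        whr_only = RiskFactorProfile(age=60, sex="male", sbp=140, whr=0.98)
        assert anthropometric_delta(with_all, deltas) == anthropometric_delta(whr_only, deltas)

    def test_fallback_bmi_before_waist(self, deltas):
        bmi_and_waist = RiskFactorProfile(age=60, sex="male", sbp=140, bmi=27,
                                          waist_circumference_cm=150)
        bmi_only = RiskFactorProfile(age=60, sex="male", sbp=140, bmi=27)
        assert anthropometric_delta(bmi_and_waist, deltas) == \
            anthropometric_delta(bmi_only, deltas)

    def test_all_absent_scores_zero(self, deltas, base_profile):
        assert anthropometric_delta(base_profile, deltas) == 0.0


class TestRiskometerDeltas:
    @pytest.mark.parametrize("key,attr,expected", [
        ("non_caucasian", "non_caucasian", 0.20),
        ("poor_diet", "poor_diet", 0.20),
        ("high_alcohol", "high_alcohol", 0.10),
        ("low_physical_activity", "low_physical_activity", 0.10),
        ("family_history", "family_history_stroke_or_mi", 0.05),
    ])
    def test_lp_delta_exactness(self, deltas, base_profile, key, attr, expected):
        toggled = replace(base_profile, **{attr: True})
        assert riskometer_lp_delta(toggled, deltas) == expected
        assert riskometer_lp_delta(base_profile, deltas) == 0.0

    @pytest.mark.parametrize("attr,hr", [
        ("cognitive_problems", 1.80),
        ("memory_problems", 1.40),
        ("previous_tbi", 1.20),
    ])
    def test_multiplier_enters_as_log(self, deltas, base_profile, attr, hr):
        toggled = replace(base_profile, **{attr: True})
        assert riskometer_lp_delta(toggled, deltas) == pytest.approx(math.log(hr), rel=1e-12)

    def test_memory_term_suppressed_by_cognitive(self, deltas, base_profile):
        cognitive = replace(base_profile, cognitive_problems=True)
        # memory flag cannot coexist; cognitive alone must use the 1.80 term only
        assert riskometer_lp_delta(cognitive, deltas) == pytest.approx(math.log(1.8), rel=1e-12)

    def test_unknown_delta_key_is_config_error(self, base_profile):
        config = RiskometerDeltaConfig(lp_deltas={"vaping": 0.1})
        with pytest.raises(ConfigError, match="vaping"):
            riskometer_lp_delta(base_profile, config)

    def test_negative_delta_rejected(self):
        with pytest.raises(ConfigError, match=">= 0"):
            RiskometerDeltaConfig(lp_deltas={"poor_diet": -0.1})

    def test_submultiplicative_rr_rejected(self):
        with pytest.raises(ConfigError, match=">= 1"):
            RiskometerDeltaConfig(rr_multipliers={"previous_tbi": 0.9})


class TestRiskometerRisk:
    def test_no_deltas_equals_fsrs(self, toy_coeffs_male, deltas, base_profile):
        rm = riskometer_risk(base_profile, toy_coeffs_male, deltas, 10)
        fs = fsrs_risk(base_profile, toy_coeffs_male, 10)
        assert rm.absolute_risk_percent == fs.absolute_risk_percent
        assert rm.linear_predictor == fs.linear_predictor

    def test_prior_stroke_adds_10_points_at_5_years(self, toy_coeffs_male, deltas):
        # moderate-risk profile keeps both sides below the 100% cap
        moderate = RiskFactorProfile(age=30, sex="male", sbp=100)
        without = riskometer_risk(moderate, toy_coeffs_male, deltas, 5)
        with_flag = riskometer_risk(
            replace(moderate, previous_stroke_or_tia=True), toy_coeffs_male, deltas, 5
        )
        assert without.absolute_risk_percent + 10 < 100
        diff = with_flag.absolute_risk_percent - without.absolute_risk_percent
        assert diff == pytest.approx(10.0, abs=1e-9)

    def test_prior_stroke_adds_15_points_at_10_years(self, toy_coeffs_male, deltas):
        moderate = RiskFactorProfile(age=30, sex="male", sbp=100)
        without = riskometer_risk(moderate, toy_coeffs_male, deltas, 10)
        with_flag = riskometer_risk(
            replace(moderate, previous_stroke_or_tia=True), toy_coeffs_male, deltas, 10
        )
        assert without.absolute_risk_percent + 15 < 100
        diff = with_flag.absolute_risk_percent - without.absolute_risk_percent
        assert diff == pytest.approx(15.0, abs=1e-9)

    def test_prior_stroke_capped_at_100(self, deltas):
        coeffs = CoefficientSet(sex="male", betas={"age": 0.2}, covariate_means={},
                                baseline_survival={5: 0.5, 10: 0.3})
        profile = RiskFactorProfile(age=95, sex="male", sbp=200,
                                    previous_stroke_or_tia=True)
        est = riskometer_risk(profile, coeffs, deltas, 5)
        assert est.absolute_risk_percent == 100.0

    def test_poor_diet_lp_difference(self, toy_coeffs_male, deltas, base_profile):
        plain = riskometer_risk(base_profile, toy_coeffs_male, deltas, 5)
        dieted = riskometer_risk(replace(base_profile, poor_diet=True),
                                 toy_coeffs_male, deltas, 5)
        assert dieted.linear_predictor - plain.linear_predictor == pytest.approx(0.20, abs=1e-12)

    def test_dominance_over_fsrs(self, toy_coeffs_male, deltas, rng):
        for _ in range(50):
            profile = random_profile(rng, sex="male")
            rm = riskometer_risk(profile, toy_coeffs_male, deltas, 5).absolute_risk_percent
            fs = fsrs_risk(profile, toy_coeffs_male, 5).absolute_risk_percent
            assert rm >= fs


class TestBaselineReferenceRisk:
    def test_equals_reference_profile_risk(self, toy_coeffs_male, deltas):
        direct = riskometer_risk(
            reference_profile(65, "male", toy_coeffs_male), toy_coeffs_male, deltas, 10
        ).absolute_risk_percent
        assert baseline_reference_risk(65, "male", toy_coeffs_male, deltas, 10) == direct

    def test_nondecreasing_in_age(self, toy_coeffs_male, deltas):
        risks = [baseline_reference_risk(a, "male", toy_coeffs_male, deltas, 10)
                 for a in (30, 45, 60, 75, 90)]
        assert all(a <= b for a, b in zip(risks, risks[1:]))

    def test_toy_closed_form(self, toy_coeffs_male, deltas):
        lp = 0.05 * 40 + 0.01 * 120
        expected = 100 * (1 - 0.97 ** math.exp(lp))
        assert baseline_reference_risk(40, "male", toy_coeffs_male, deltas, 5) == \
            pytest.approx(expected, rel=1e-12)


class TestScoreCohort:
    def test_singleton_matches_scalar_call(self, toy_config, base_profile):
        result = score_cohort([base_profile], toy_config, 5)
        scalar = riskometer_risk(
            base_profile, toy_config.coeffs_for("male"), toy_config.deltas, 5
        ).absolute_risk_percent
        assert result.risks_percent[0] == scalar

    def test_order_equivariance(self, toy_config, rng):
        profiles = [random_profile(rng) for _ in range(30)]
        risks = score_cohort(profiles, toy_config, 5).risks_percent
        perm = rng.permutation(30)
        permuted = score_cohort([profiles[i] for i in perm], toy_config, 5).risks_percent
        np.testing.assert_array_equal(permuted, risks[perm])

    def test_matches_scalar_loop(self, toy_config, rng):
        profiles = [random_profile(rng) for _ in range(100)]
        result = score_cohort(profiles, toy_config, 10).risks_percent
        expected = [
            riskometer_risk(p, toy_config.coeffs_for(p.sex), toy_config.deltas, 10)
            .absolute_risk_percent
            for p in profiles
        ]
        np.testing.assert_allclose(result, expected, rtol=0)

    def test_empty_cohort_errors(self, toy_config):
        with pytest.raises(ScoringError, match="empty"):
            score_cohort([], toy_config, 5)

    def test_fsrs_route(self, toy_config, base_profile):
        result = score_cohort([base_profile], toy_config, 5, model="fsrs")
        expected = fsrs_risk(base_profile, toy_config.coeffs_for("male"), 5)
        assert result.risks_percent[0] == expected.absolute_risk_percent


class TestDefaultConfig:
    def test_packaged_json_matches_code_default(self, default_config):
        from strokerisk.cli_io import load_default_model_config

        loaded = load_default_model_config()
        assert loaded.by_sex["male"].betas == dict(default_config.by_sex["male"].betas)
        assert loaded.by_sex["female"].betas == dict(default_config.by_sex["female"].betas)
        assert loaded.deltas.lp_deltas == dict(default_config.deltas.lp_deltas)
        assert loaded.deltas.prior_stroke_percent_points == {5: 10.0, 10: 15.0}

    def test_default_deltas_are_printed_values(self, default_config):
        assert default_config.deltas.lp_deltas["poor_diet"] == 0.20
        assert default_config.deltas.rr_multipliers["cognitive_problems"] == 1.80
        assert default_config.deltas.whr_rule.threshold_male == 0.96
        assert default_config.deltas.waist_rule.threshold_female_cm == 89.0

    def test_default_risks_are_sensible(self, default_config):
        profile = RiskFactorProfile(age=65, sex="male", sbp=150, smoking="current",
                                    diabetes=True)
        est = riskometer_risk(profile, default_config.coeffs_for("male"),
                              default_config.deltas, 10)
        assert 0 < est.baseline_risk_percent < est.absolute_risk_percent < 100
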