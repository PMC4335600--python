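"""Absolute stroke-risk scoring.

The base model is a sex-specific Cox-style prediction equation: a linear
predictor on the log-hazard scale is mapped to an absolute risk through a
baseline survival function,

    risk(t) = 1 - S0(t) ** exp(lp - sum_i beta_i * mean_i).

The extended ("riskometer") model adds further risk factors on top of the
base linear predictor:

* additive log-hazard deltas for lifestyle/ethnicity flags,
* hazard-ratio multipliers (applied as ``ln(hr)`` additions) for cognitive
  problems, memory problems and previous traumatic brain injury,
* an anthropometric term with a fallback chain waist-to-hip ratio -> BMI ->
  waist circumference,
* an absolute percentage-point addition for previous stroke/TIA (+10 points
  at the 5-year horizon, +15 at 10 years), capped at 100%.

All public risk values are percentages in [0, 100].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, CovariateError, ProfileError, ScoringError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
SMOKING_LEVELS = ("never", "ex", "current")
ETHNIC_GROUPS = ("chinese", "south_asian", "other")
HORIZONS = (5, 10)

#: exponent guard: exp() of anything above this saturates the risk at 1 anyway
_MAX_EXPONENT = 700.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskFactorProfile:
    """One person's risk-factor values.

    Booleans are risk-factor flags; ``whr``, ``bmi`` and
    ``waist_circumference_cm`` are optional anthropometrics consumed through
    a fallback chain (WHR first, then BMI, then waist circumference).
    ``memory_problems`` means memory complaints *without* cognitive problems,
    so the two flags are mutually exclusive.
    """

    age: float
    sex: str
    sbp: float
    antihypertensive_treatment: bool = False
    diabetes: bool = False
    cvd_history: bool = False
    smoking: str = "never"
    atrial_fibrillation: bool = False
    lvh: bool = False
    family_history_stroke_or_mi: bool = False
    non_caucasian: bool = False
    poor_diet: bool = False
    high_alcohol: bool = False
    low_physical_activity: bool = False
    stress: bool = False
    previous_stroke_or_tia: bool = False
    cognitive_problems: bool = False
    memory_problems: bool = False
    previous_tbi: bool = False
    whr: float | None = None
    bmi: float | None = None
    waist_circumference_cm: float | None = None
    ethnic_group: str = "other"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ProfileError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise ProfileError(
                f"smoking must be one of {SMOKING_LEVELS}, got {self.smoking!r}"
            )
        if self.ethnic_group not in ETHNIC_GROUPS:
            raise ProfileError(
                f"ethnic_group must be one of {ETHNIC_GROUPS}, got {self.ethnic_group!r}"
            )
        if not (self.age >= 20):
            raise ProfileError(f"age must be >= 20 years, got {self.age}")
        if not (self.sbp > 0):
            raise ProfileError(f"sbp must be positive, got {self.sbp}")
        for name in ("whr", "bmi", "waist_circumference_cm"):
            value = getattr(self, name)
            if value is not None and not (value > 0):
                raise ProfileError(f"{name} must be positive when present, got {value}")
        if self.cognitive_problems and self.memory_problems:
            raise ProfileError(
                "cognitive_problems and memory_problems cannot both be true; "
                "memory_problems is defined as memory complaints without "
                "cognitive problems"
            )


@dataclass(frozen=True)
class CoefficientSet:
    """Sex-specific base-model coefficients.

    ``betas`` maps covariate names (see :func:`derive_covariates`) to
    log-hazard coefficients, ``covariate_means`` holds the centering means
    and ``baseline_survival`` maps a horizon in years to S0(t).
    """

    sex: str
    betas: Mapping[str, float]
    covariate_means: Mapping[str, float]
    baseline_survival: Mapping[int, float]
    reference_sbp: float = 120.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for horizon, s0 in self.baseline_survival.items():
            if not (0.0 < s0 <= 1.0):
                raise ConfigError(
                    f"baseline survival S0({horizon}) must be in (0, 1], got {s0}"
                )
        s5 = self.baseline_survival.get(5)
        s10 = self.baseline_survival.get(10)
        if s5 is not None and s10 is not None and s10 > s5:
            raise ConfigError(
                f"S0(10)={s10} must not exceed S0(5)={s5}: survival decreases in time"
            )
        if not (self.reference_sbp > 0):
            raise ConfigError(f"reference_sbp must be positive, got {self.reference_sbp}")

    def baseline_survival_at(self, horizon: int) -> float:
        """S0 at ``horizon``; S0(5) falls back to sqrt(S0(10)) (constant hazard)."""
        if horizon in self.baseline_survival:
            return float(self.baseline_survival[horizon])
        if horizon == 5 and 10 in self.baseline_survival:
            derived = float(self.baseline_survival[10]) ** 0.5
            logger.info(
                "S0(5) not configured for sex=%s; derived %.6f from S0(10) "
                "assuming a constant baseline hazard", self.sex, derived,
            )
            return derived
        raise ConfigError(
            f"no baseline survival configured for horizon {horizon} "
            f"(available: {sorted(self.baseline_survival)})"
        )


@dataclass(frozen=True)
class WhrRule:
    threshold_male: float = 0.96
    threshold_female: float = 0.80
    base_delta: float = 0.20
    per_unit_delta: float = 0.10
    unit: float = 0.01


@dataclass(frozen=True)
class BmiRule:
    threshold_chinese: float = 24.0
    threshold_south_asian: float = 23.0
    threshold_other: float = 25.0
    per_unit_delta: float = 0.10
    base_rr: float = 1.02
    # off by default: the operational variable table defines the BMI score as
    # 0.10 per unit above threshold with no base term
    include_base_term: bool = False
    unit: float = 1.0


@dataclass(frozen=True)
class WaistRule:
    threshold_male_cm: float = 103.0
    threshold_female_cm: float = 89.0
    per_unit_rr: float = 1.02
    unit: float = 1.0


def _default_lp_deltas() -> dict[str, float]:
    return {
        "non_caucasian": 0.20,
        "poor_diet": 0.20,
        "high_alcohol": 0.10,
        "low_physical_activity": 0.10,
        "family_history": 0.05,
        "stress": 0.0,  # listed as a variable but carries no published weight
    }


def _default_rr_multipliers() -> dict[str, float]:
    return {
        "cognitive_problems": 1.80,
        "memory_only": 1.40,
        "previous_tbi": 1.20,
    }


def _default_prior_stroke_points() -> dict[int, float]:
    return {5: 10.0, 10: 15.0}


@dataclass(frozen=True)
class RiskometerDeltaConfig:
    """Add-on terms for the extended model; defaults are the published values."""

    lp_deltas: Mapping[str, float] = field(default_factory=_default_lp_deltas)
    rr_multipliers: Mapping[str, float] = field(default_factory=_default_rr_multipliers)
    prior_stroke_percent_points: Mapping[int, float] = field(
        default_factory=_default_prior_stroke_points
    )
    whr_rule: WhrRule = field(default_factory=WhrRule)
    bmi_rule: BmiRule = field(default_factory=BmiRule)
    waist_rule: WaistRule = field(default_factory=WaistRule)

    def __post_init__(self) -> None:
        for key, delta in self.lp_deltas.items():
            if delta < 0:
                raise ConfigError(f"lp delta {key!r} must be >= 0, got {delta}")
        for key, hr in self.rr_multipliers.items():
            if hr < 1:
                raise ConfigError(f"risk multiplier {key!r} must be >= 1, got {hr}")
        for horizon, pts in self.prior_stroke_percent_points.items():
            if pts < 0:
                raise ConfigError(
                    f"prior-stroke points for horizon {horizon} must be >= 0, got {pts}"
                )
        for rule_name, thresholds in (
            ("whr_rule", (self.whr_rule.threshold_male, self.whr_rule.threshold_female)),
            ("bmi_rule", (self.bmi_rule.threshold_chinese,
                          self.bmi_rule.threshold_south_asian,
                          self.bmi_rule.threshold_other)),
            ("waist_rule", (self.waist_rule.threshold_male_cm,
                            self.waist_rule.threshold_female_cm)),
        ):
            if any(t <= 0 for t in thresholds):
                raise ConfigError(f"{rule_name} thresholds must be positive")


@dataclass(frozen=True)
class RiskEstimate:
    """An absolute-risk prediction plus the matched no-risk-factor baseline."""

    horizon: int
    absolute_risk_percent: float
    baseline_risk_percent: float
    linear_predictor: float
    model: str


@dataclass(frozen=True)
class ModelConfig:
    """A named model: per-sex coefficient sets plus the delta table."""

    model_name: str
    by_sex: Mapping[str, CoefficientSet]
    deltas: RiskometerDeltaConfig = field(default_factory=RiskometerDeltaConfig)

    def __post_init__(self) -> None:
        missing = [s for s in SEXES if s not in self.by_sex]
        if missing:
            raise ConfigError(f"model {self.model_name!r} missing coefficient sets for {missing}")
        for sex, coeffs in self.by_sex.items():
            if coeffs.sex != sex:
                raise ConfigError(
                    f"coefficient set under key {sex!r} declares sex {coeffs.sex!r}"
                )

    def coeffs_for(self, sex: str) -> CoefficientSet:
        try:
            return self.by_sex[sex]
        except KeyError:
            raise ConfigError(f"no coefficient set for sex {sex!r}") from None


# ---------------------------------------------------------------------------
# covariate derivation and the linear predictor
# ---------------------------------------------------------------------------

def derive_covariates(profile: RiskFactorProfile) -> dict[str, float]:
    """Numeric covariates the base-model betas may reference.

    Smoking enters as the current-smoker indicator; an ``ex_smoker``
    indicator is exposed as well for coefficient sets that declare one.
    """
    return {
        "age": float(profile.age),
        "sbp": float(profile.sbp),
        "antihypertensive_treatment": float(profile.antihypertensive_treatment),
        "diabetes": float(profile.diabetes),
        "cvd_history": float(profile.cvd_history),
        "current_smoker": float(profile.smoking == "current"),
        "ex_smoker": float(profile.smoking == "ex"),
        "atrial_fibrillation": float(profile.atrial_fibrillation),
        "lvh": float(profile.lvh),
    }


def linear_predictor(profile: RiskFactorProfile, coeffs: CoefficientSet) -> float:
    """Uncentered base-model linear predictor ``sum_i beta_i * x_i``."""
    if coeffs.sex != profile.sex:
        raise ConfigError(
            f"profile sex {profile.sex!r} does not match coefficient set sex {coeffs.sex!r}"
        )
    covariates = derive_covariates(profile)
    total = 0.0
    for name, beta in coeffs.betas.items():
        if name not in covariates:
            raise CovariateError(
                f"coefficient references covariate {name!r} which cannot be "
                f"derived from a risk-factor profile (known: {sorted(covariates)})"
            )
        total += beta * covariates[name]
    return total


def risk_from_lp(lp: float, coeffs: CoefficientSet, horizon: int) -> float:
    """Absolute risk fraction ``1 - S0(t)^exp(lp - sum beta*mean)`` in [0, 1]."""
    s0 = coeffs.baseline_survival_at(horizon)
    offset = sum(
        beta * coeffs.covariate_means.get(name, 0.0)
        for name, beta in coeffs.betas.items()
    )
    centered = lp - offset
    risk = 1.0 - s0 ** math.exp(min(centered, _MAX_EXPONENT))
    if risk < 0.0 or risk > 1.0:  # unreachable for valid S0; guard for NaN/overflow
        logger.warning("risk %.6g outside [0, 1]; clipping", risk)
        risk = min(max(risk, 0.0), 1.0)
    return risk


# ---------------------------------------------------------------------------
# the extended-model deltas
# ---------------------------------------------------------------------------

#: lp-delta config key -> profile attribute carrying the flag
_LP_DELTA_ATTRS = {
    "non_caucasian": "non_caucasian",
    "poor_diet": "poor_diet",
    "high_alcohol": "high_alcohol",
    "low_physical_activity": "low_physical_activity",
    "family_history": "family_history_stroke_or_mi",
    "stress": "stress",
}

_RR_KEYS = ("cognitive_problems", "memory_only", "previous_tbi")


def anthropometric_delta(profile: RiskFactorProfile, config: RiskometerDeltaConfig) -> float:
    """Log-hazard addition from the anthropometric fallback chain.

    Waist-to-hip ratio takes precedence; if absent, BMI; if both absent,
    waist circumference; all absent scores 0. Each rule contributes 0 at or
    below its threshold.
    """
    if profile.whr is not None:
        rule = config.whr_rule
        threshold = rule.threshold_male if profile.sex == "male" else rule.threshold_female
        if profile.whr <= threshold:
            return 0.0
        return rule.base_delta + rule.per_unit_delta * (profile.whr - threshold) / rule.unit
    if profile.bmi is not None:
        rule = config.bmi_rule
        threshold = {
            "chinese": rule.threshold_chinese,
            "south_asian": rule.threshold_south_asian,
            "other": rule.threshold_other,
        }[profile.ethnic_group]
        excess = max(0.0, profile.bmi - threshold)
        if excess == 0.0:
            return 0.0
        delta = rule.per_unit_delta * excess / rule.unit
        if rule.include_base_term:
            delta += math.log(rule.base_rr)
        return delta
    if profile.waist_circumference_cm is not None:
        rule = config.waist_rule
        threshold = rule.threshold_male_cm if profile.sex == "male" else rule.threshold_female_cm
        excess = max(0.0, profile.waist_circumference_cm - threshold)
        return math.log(rule.per_unit_rr) * excess / rule.unit
    return 0.0


def riskometer_lp_delta(profile: RiskFactorProfile, config: RiskometerDeltaConfig) -> float:
    """Total log-hazard addition of the extended model over the base model."""
    total = 0.0
    for key, delta in config.lp_deltas.items():
        attr = _LP_DELTA_ATTRS.get(key)
        if attr is None:
            raise ConfigError(
                f"unknown lp delta key {key!r}; known keys: {sorted(_LP_DELTA_ATTRS)}"
            )
        if getattr(profile, attr):
            total += delta
    for key, hr in config.rr_multipliers.items():
        if key not in _RR_KEYS:
            raise ConfigError(
                f"unknown risk-multiplier key {key!r}; known keys: {sorted(_RR_KEYS)}"
            )
    if profile.cognitive_problems:
        total += math.log(config.rr_multipliers.get("cognitive_problems", 1.0))
    elif profile.memory_problems:
        total += math.log(config.rr_multipliers.get("memory_only", 1.0))
    if profile.previous_tbi:
        total += math.log(config.rr_multipliers.get("previous_tbi", 1.0))
    total += anthropometric_delta(profile, config)
    return total


# ---------------------------------------------------------------------------
# risk estimates
# ---------------------------------------------------------------------------

def reference_profile(age: float, sex: str, coeffs: CoefficientSet) -> RiskFactorProfile:
    """Same-age, same-sex profile with every risk factor at its reference level."""
    return RiskFactorProfile(age=age, sex=sex, sbp=coeffs.reference_sbp)


def _check_horizon(horizon: int) -> None:
    if horizon not in HORIZONS:
        raise ConfigError(f"horizon must be one of {HORIZONS}, got {horizon!r}")


def fsrs_risk(
    profile: RiskFactorProfile, coeffs: CoefficientSet, horizon: int
) -> RiskEstimate:
    """Base-model absolute risk, with the no-risk-factor baseline for comparison."""
    _check_horizon(horizon)
    lp = linear_predictor(profile, coeffs)
    risk = 100.0 * risk_from_lp(lp, coeffs, horizon)
    ref = reference_profile(profile.age, profile.sex, coeffs)
    baseline = 100.0 * risk_from_lp(linear_predictor(ref, coeffs), coeffs, horizon)
    return RiskEstimate(
        horizon=horizon,
        absolute_risk_percent=risk,
        baseline_risk_percent=baseline,
        linear_predictor=lp,
        model="fsrs",
    )


def riskometer_risk(
    profile: RiskFactorProfile,
    coeffs: CoefficientSet,
    delta_config: RiskometerDeltaConfig,
    horizon: int,
) -> RiskEstimate:
    """Extended-model absolute risk (base lp + deltas + prior-stroke points)."""
    _check_horizon(horizon)
    lp = linear_predictor(profile, coeffs) + riskometer_lp_delta(profile, delta_config)
    risk = 100.0 * risk_from_lp(lp, coeffs, horizon)
    if profile.previous_stroke_or_tia:
        try:
            points = delta_config.prior_stroke_percent_points[horizon]
        except KeyError:
            raise ConfigError(
                f"no prior-stroke percentage points configured for horizon {horizon}"
            ) from None
        risk = min(100.0, risk + points)
    ref = reference_profile(profile.age, profile.sex, coeffs)
    baseline_lp = linear_predictor(ref, coeffs) + riskometer_lp_delta(ref, delta_config)
    baseline = 100.0 * risk_from_lp(baseline_lp, coeffs, horizon)
    return RiskEstimate(
        horizon=horizon,
        absolute_risk_percent=risk,
        baseline_risk_percent=baseline,
        linear_predictor=lp,
        model="riskometer",
    )


def baseline_reference_risk(
    age: float,
    sex: str,
    coeffs: CoefficientSet,
    delta_config: RiskometerDeltaConfig,
    horizon: int,
) -> float:
    """Risk percent for a person of this age/sex with no risk factors."""
    profile = reference_profile(age, sex, coeffs)
    return riskometer_risk(profile, coeffs, delta_config, horizon).absolute_risk_percent


def estimate(
    profile: RiskFactorProfile,
    config: ModelConfig,
    horizon: int,
    model: str | None = None,
) -> RiskEstimate:
    """Score one profile with the named model ('fsrs' or 'riskometer')."""
    name = model or config.model_name
    coeffs = config.coeffs_for(profile.sex)
    if name == "fsrs":
        return fsrs_risk(profile, coeffs, horizon)
    if name == "riskometer":
        return riskometer_risk(profile, coeffs, config.deltas, horizon)
    raise ConfigError(f"unknown model {name!r}; expected 'fsrs' or 'riskometer'")


# ---------------------------------------------------------------------------
# cohort scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RowFailure:
    row: int
    reason: str


@dataclass(frozen=True)
class ScoringResult:
    """Risk percents aligned to input rows; skipped rows carry NaN."""

    risks_percent: np.ndarray
    failures: tuple[RowFailure, ...] = ()


def score_cohort(
    profiles: Sequence[RiskFactorProfile] | Iterable[RiskFactorProfile],
    config: ModelConfig,
    horizon: int,
    model: str | None = None,
    on_invalid: str = "raise",
) -> ScoringResult:
    """Score every profile, preserving order.

    ``on_invalid='raise'`` fails fast on the first invalid row;
    ``'skip'`` records the failure and emits NaN for that row.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError(f"on_invalid must be 'raise' or 'skip', got {on_invalid!r}")
    profiles = list(profiles)
    if not profiles:
        raise ScoringError("cannot score an empty cohort")
    risks = np.full(len(profiles), np.nan)
    failures: list[RowFailure] = []
    for i, profile in enumerate(profiles):
        try:
            risks[i] = estimate(profile, config, horizon, model=model).absolute_risk_percent
        except (ProfileError, CovariateError) as exc:
            if on_invalid == "raise":
                raise ScoringError(f"row {i}: {exc}") from exc
            failures.append(RowFailure(row=i, reason=str(exc)))
            logger.warning("skipping row %d: %s", i, exc)
    return ScoringResult(risks_percent=risks, failures=tuple(failures))


# ---------------------------------------------------------------------------
# shipped default configuration
# ---------------------------------------------------------------------------

_PROVENANCE = (
    "Approximate transcription of the published Framingham stroke probability "
    "equations (Cox form, 10-year baseline survival; 5-year derived under a "
    "constant baseline hazard). Shipped as a convenience default only - "
    "verify against the original publication before any substantive use."
)


def default_model_config(model_name: str = "riskometer") -> ModelConfig:
    """Default per-sex coefficient sets and the published delta table."""
    male = CoefficientSet(
        sex="male",
        betas={
            "age": 0.0505,
            "sbp": 0.0140,
            "antihypertensive_treatment": 0.3263,
            "diabetes": 0.3384,
            "current_smoker": 0.5147,
            "cvd_history": 0.5212,
            "atrial_fibrillation": 0.6108,
            "lvh": 0.7778,
        },
        covariate_means={
            "age": 64.9,
            "sbp": 139.0,
            "antihypertensive_treatment": 0.26,
            "diabetes": 0.09,
            "current_smoker": 0.27,
            "cvd_history": 0.21,
            "atrial_fibrillation": 0.02,
            "lvh": 0.04,
        },
        baseline_survival={10: 0.945},
        provenance=_PROVENANCE,
    )
    female = CoefficientSet(
        sex="female",
        betas={
            "age": 0.0665,
            "sbp": 0.0138,
            "antihypertensive_treatment": 0.4300,
            "diabetes": 0.3870,
            "current_smoker": 0.5922,
            "cvd_history": 0.4610,
            "atrial_fibrillation": 0.8410,
            "lvh": 0.4340,
        },
        covariate_means={
            "age": 66.1,
            "sbp": 137.0,
            "antihypertensive_treatment": 0.31,
            "diabetes": 0.08,
            "current_smoker": 0.24,
            "cvd_history": 0.11,
            "atrial_fibrillation": 0.03,
            "lvh": 0.03,
        },
        baseline_survival={10: 0.965},
        provenance=_PROVENANCE,
    )
    return ModelConfig(
        model_name=model_name,
        by_sex={"male": male, "female": female},
        deltas=RiskometerDeltaConfig(),
    )


def with_model_name(config: ModelConfig, model_name: str) -> ModelConfig:
    return replace(config, model_name=model_name)
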