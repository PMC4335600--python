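import numpy as np
import pytest

from strokerisk.risk_models import (
    CoefficientSet,
    ModelConfig,
    RiskFactorProfile,
    RiskometerDeltaConfig,
    default_model_config,
)


@pytest.fixture
def toy_coeffs_male():
    """Small uncentered toy coefficient set for exact hand computations."""
    return CoefficientSet(
        sex="male",
        betas={"age": 0.05, "sbp": 0.01, "diabetes": 0.3, "current_smoker": 0.5,
               "atrial_fibrillation": 0.6},
        covariate_means={},
        baseline_survival={5: 0.97, 10: 0.90},
        reference_sbp=120.0,
    )


@pytest.fixture
def toy_coeffs_female():
    return CoefficientSet(
        sex="female",
        betas={"age": 0.06, "sbp": 0.012},
        covariate_means={},
        baseline_survival={5: 0.98, 10: 0.94},
        reference_sbp=120.0,
    )


@pytest.fixture
def toy_config(toy_coeffs_male, toy_coeffs_female):
    return ModelConfig(
        model_name="riskometer",
        by_sex={"male": toy_coeffs_male, "female": toy_coeffs_female},
        deltas=RiskometerDeltaConfig(),
    )


@pytest.fixture
def default_config():
    return default_model_config()


@pytest.fixture
def deltas():
    return RiskometerDeltaConfig()


@pytest.fixture
def base_profile():
    """Male profile with no extended-model factors active."""
    return RiskFactorProfile(age=60.0, sex="male", sbp=140.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(rng, **overrides):
    """Random but valid profile; anthropometrics absent unless overridden."""
    kwargs = dict(
        age=float(rng.uniform(20, 95)),
        sex=rng.choice(["male", "female"]),
        sbp=float(rng.uniform(90, 220)),
        antihypertensive_treatment=bool(rng.random() < 0.3),
        diabetes=bool(rng.random() < 0.2),
        cvd_history=bool(rng.random() < 0.2),
        smoking=rng.choice(["never", "ex", "current"]),
        atrial_fibrillation=bool(rng.random() < 0.1),
        lvh=bool(rng.random() < 0.1),
        family_history_stroke_or_mi=bool(rng.random() < 0.3),
        non_caucasian=bool(rng.random() < 0.3),
        poor_diet=bool(rng.random() < 0.5),
        high_alcohol=bool(rng.random() < 0.3),
        low_physical_activity=bool(rng.random() < 0.5),
        stress=bool(rng.random() < 0.3),
        previous_stroke_or_tia=bool(rng.random() < 0.15),
        cognitive_problems=bool(rng.random() < 0.1),
        previous_tbi=bool(rng.random() < 0.1),
    )
    kwargs["memory_problems"] = (not kwargs["cognitive_problems"]) and bool(rng.random() < 0.2)
    kwargs.update(overrides)
    return RiskFactorProfile(**kwargs)
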