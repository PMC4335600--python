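"""Seeded synthetic cohorts for end-to-end testing of the scoring and
validation machinery.

Profiles are drawn from independent marginals (truncated normals for
continuous variables, Bernoulli for flags); outcomes come either from a risk
model (calibration-faithful) or from a constant event rate (null). Presets
emulate the marginal summaries of the three validation cohorts described in
the source study's baseline table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigError, DataError
from .risk_models import (
    HORIZONS,
    ModelConfig,
    RiskFactorProfile,
    score_cohort,
)

# physiologic plausibility bounds used to truncate the normal marginals
TRUNCATION_BOUNDS = {
    "age": (20.0, 100.0),
    "sbp": (70.0, 260.0),
    "bmi": (14.0, 60.0),
    "whr": (0.5, 1.4),
    "waist": (50.0, 180.0),
}

#: λ cap for event-time simulation; corresponds to risk ≈ 1 - 1e-12
_RISK_CAP = 1.0 - 1e-12

_BINARY_FACTORS = (
    "antihypertensive_treatment",
    "diabetes",
    "cvd_history",
    "atrial_fibrillation",
    "lvh",
    "family_history_stroke_or_mi",
    "non_caucasian",
    "poor_diet",
    "high_alcohol",
    "low_physical_activity",
    "stress",
    "previous_stroke_or_tia",
    "cognitive_problems",
    "memory_problems",
    "previous_tbi",
)

PerSex = Mapping[str, tuple[float, float]]


@dataclass(frozen=True)
class CohortSpec:
    """Marginal description of a cohort to simulate."""

    name: str
    n: int
    seed: int
    sex_ratio: float = 0.5  # male fraction
    age: PerSex = field(default_factory=dict)  # sex -> (mean, sd)
    sbp: PerSex = field(default_factory=dict)
    bmi: PerSex | None = None
    whr: PerSex | None = None
    waist: PerSex | None = None
    prevalences: Mapping[str, float] = field(default_factory=dict)
    smoking: Mapping[str, float] = field(
        default_factory=lambda: {"never": 0.5, "ex": 0.2, "current": 0.3}
    )
    target_event_rate: float | str = "model"
    horizon: int = 5
    outcome_mode: str = "times"  # "times" or "binary"
    censoring_rate: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        if self.n < 1:
            problems.append(f"n must be >= 1, got {self.n}")
        if not (0.0 <= self.sex_ratio <= 1.0):
            problems.append(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        for sex in ("male", "female"):
            if sex not in self.age:
                problems.append(f"age marginal missing for {sex}")
            if sex not in self.sbp:
                problems.append(f"sbp marginal missing for {sex}")
        for label, marginal in (("age", self.age), ("sbp", self.sbp),
                                ("bmi", self.bmi), ("whr", self.whr),
                                ("waist", self.waist)):
            if marginal is None:
                continue
            for sex, (mean, sd) in marginal.items():
                if sd <= 0:
                    problems.append(f"{label} sd for {sex} must be > 0, got {sd}")
        for factor, p in self.prevalences.items():
            if factor not in _BINARY_FACTORS:
                problems.append(f"unknown binary factor {factor!r}")
            elif not (0.0 <= p <= 1.0):
                problems.append(f"prevalence of {factor} must be in [0, 1], got {p}")
        if abs(sum(self.smoking.values()) - 1.0) > 1e-9:
            problems.append("smoking distribution must sum to 1")
        if set(self.smoking) - {"never", "ex", "current"}:
            problems.append("smoking keys must be never/ex/current")
        if self.horizon not in HORIZONS:
            problems.append(f"horizon must be one of {HORIZONS}, got {self.horizon}")
        if isinstance(self.target_event_rate, str):
            if self.target_event_rate != "model":
                problems.append("target_event_rate must be a rate in [0,1] or 'model'")
        elif not (0.0 <= self.target_event_rate <= 1.0):
            problems.append(f"target_event_rate must be in [0, 1], got {self.target_event_rate}")
        if self.outcome_mode not in ("times", "binary"):
            problems.append("outcome_mode must be 'times' or 'binary'")
        if not (0.0 <= self.censoring_rate < 1.0):
            problems.append(f"censoring_rate must be in [0, 1), got {self.censoring_rate}")
        if problems:
            raise ConfigError("invalid cohort spec: " + "; ".join(problems))


@dataclass
class Cohort:
    """Simulated profiles with follow-up and event indicators."""

    profiles: list[RiskFactorProfile]
    follow_up_years: np.ndarray
    events: np.ndarray
    true_risk_percent: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.profiles)
        self.follow_up_years = np.asarray(self.follow_up_years, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if len(self.follow_up_years) != n or len(self.events) != n:
            raise DataError("follow-up and event vectors must align with profiles")
        if n and (self.follow_up_years <= 0).any():
            raise DataError("follow-up times must be > 0")

    def __len__(self) -> int:
        return len(self.profiles)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _column_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """One deterministic sub-stream per column, derived from a single seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _sample_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], size: int
) -> np.ndarray:
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _per_sex_column(
    rng: np.random.Generator,
    marginal: PerSex | None,
    sexes: np.ndarray,
    bounds: tuple[float, float],
) -> np.ndarray | None:
    if marginal is None:
        return None
    out = np.full(len(sexes), np.nan)
    for sex, (mean, sd) in marginal.items():
        mask = sexes == sex
        out[mask] = _sample_truncnorm(rng, mean, sd, bounds, int(mask.sum()))
    return out


def sample_profiles(spec: CohortSpec) -> list[RiskFactorProfile]:
    """Draw ``spec.n`` profiles; deterministic for a fixed spec and seed."""
    columns = ["sex", "age", "sbp", "bmi", "whr", "waist", "smoking", *_BINARY_FACTORS]
    rngs = _column_rngs(spec.seed, columns)
    n = spec.n
    sexes = np.where(rngs["sex"].random(n) < spec.sex_ratio, "male", "female")
    age = _per_sex_column(rngs["age"], spec.age, sexes, TRUNCATION_BOUNDS["age"])
    sbp = _per_sex_column(rngs["sbp"], spec.sbp, sexes, TRUNCATION_BOUNDS["sbp"])
    bmi = _per_sex_column(rngs["bmi"], spec.bmi, sexes, TRUNCATION_BOUNDS["bmi"])
    whr = _per_sex_column(rngs["whr"], spec.whr, sexes, TRUNCATION_BOUNDS["whr"])
    waist = _per_sex_column(rngs["waist"], spec.waist, sexes, TRUNCATION_BOUNDS["waist"])
    levels = ("never", "ex", "current")
    probs = [spec.smoking.get(level, 0.0) for level in levels]
    smoking = rngs["smoking"].choice(levels, size=n, p=probs)
    flags = {
        factor: rngs[factor].random(n) < spec.prevalences.get(factor, 0.0)
        for factor in _BINARY_FACTORS
    }
    # a profile cannot carry both flags: memory complaints are only recorded
    # in the absence of cognitive problems
    flags["memory_problems"] &= ~flags["cognitive_problems"]

    profiles = []
    for i in range(n):
        profiles.append(
            RiskFactorProfile(
                age=float(age[i]),
                sex=str(sexes[i]),
                sbp=float(sbp[i]),
                smoking=str(smoking[i]),
                whr=None if whr is None else float(whr[i]),
                bmi=None if bmi is None else float(bmi[i]),
                waist_circumference_cm=None if waist is None else float(waist[i]),
                **{factor: bool(flags[factor][i]) for factor in _BINARY_FACTORS},
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def simulate_binary_outcomes(risks_percent: np.ndarray, seed: int) -> np.ndarray:
    """Independent Bernoulli(risk/100) event indicators."""
    risks = np.asarray(risks_percent, dtype=float)
    if (risks < 0).any() or (risks > 100).any():
        raise DataError("risks must be percents in [0, 100]")
    rng = np.random.default_rng(seed)
    return (rng.random(len(risks)) < risks / 100.0).astype(int)


def simulate_event_times(
    risks_percent: np.ndarray,
    horizon: int,
    censoring_rate: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times matched to each subject's horizon risk.

    The hazard ``lambda_i = -ln(1 - risk_i/100)/horizon`` makes
    P(event by horizon) equal the risk exactly when there is no censoring.
    A ``censoring_rate`` fraction of subjects independently receives a
    uniform censoring time on (0, horizon]; everyone else is administratively
    censored at the horizon.
    """
    risks = np.asarray(risks_percent, dtype=float)
    if (risks < 0).any() or (risks > 100).any():
        raise DataError("risks must be percents in [0, 100]")
    if not (0.0 <= censoring_rate < 1.0):
        raise DataError(f"censoring_rate must be in [0, 1), got {censoring_rate}")
    frac = np.minimum(risks / 100.0, _RISK_CAP)
    lam = -np.log1p(-frac) / horizon
    rng = np.random.default_rng(seed)
    n = len(risks)
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        event_time = np.where(lam > 0, -np.log(u) / np.where(lam > 0, lam, 1.0), np.inf)
    censor = np.full(n, float(horizon))
    censored_mask = rng.random(n) < censoring_rate
    censor[censored_mask] = rng.uniform(0.0, horizon, int(censored_mask.sum()))
    censor = np.maximum(censor, 1e-9)  # follow-up must stay positive
    events = (event_time <= censor).astype(int)
    times = np.minimum(event_time, censor)
    return times, events


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def build_cohort(
    spec: CohortSpec,
    model_config: ModelConfig | None = None,
    model: str = "riskometer",
) -> Cohort:
    """Sample profiles and attach outcomes per the spec's outcome mode."""
    profiles = sample_profiles(spec)
    outcome_seed = int(np.random.SeedSequence(spec.seed).spawn(100)[-1].generate_state(1)[0])
    true_risk = None
    if spec.target_event_rate == "model":
        if model_config is None:
            raise ConfigError("target_event_rate='model' requires a model config")
        true_risk = score_cohort(profiles, model_config, spec.horizon, model=model).risks_percent
        if spec.outcome_mode == "binary":
            events = simulate_binary_outcomes(true_risk, outcome_seed)
            times = np.full(spec.n, float(spec.horizon))
        else:
            times, events = simulate_event_times(
                true_risk, spec.horizon, spec.censoring_rate, outcome_seed
            )
    else:
        rate = 100.0 * float(spec.target_event_rate)
        events = simulate_binary_outcomes(np.full(spec.n, rate), outcome_seed)
        rng = np.random.default_rng(outcome_seed + 1)
        times = np.full(spec.n, float(spec.horizon))
        times[events == 1] = np.maximum(
            rng.uniform(0.0, spec.horizon, int(events.sum())), 1e-9
        )
    metadata = {
        "spec": _spec_metadata(spec),
        "seed": spec.seed,
        "model": model if spec.target_event_rate == "model" else None,
        "model_name": model_config.model_name if model_config is not None else None,
    }
    return Cohort(
        profiles=profiles,
        follow_up_years=times,
        events=events,
        true_risk_percent=true_risk,
        metadata=metadata,
    )


def _spec_metadata(spec: CohortSpec) -> dict:
    raw = asdict(spec)
    return raw


# ---------------------------------------------------------------------------
# presets emulating the validation cohorts' marginal summaries
# ---------------------------------------------------------------------------

def preset(name: str, n: int, seed: int, **overrides) -> CohortSpec:
    """Cohort spec presets: 'russia-like', 'rotterdam-like', 'arcos-like'.

    Continuous marginals (age, SBP, anthropometrics) and event rates follow
    the published cohort summaries; binary prevalences not printed there are
    neutral defaults and freely overridable.
    """
    if name == "russia-like":
        base = dict(
            age={"male": (50.3, 6.2), "female": (50.6, 6.4)},
            sbp={"male": (135.8, 19.4), "female": (130.8, 21.1)},
            bmi={"male": (27.8, 4.3), "female": (27.5, 5.4)},
            prevalences={
                "antihypertensive_treatment": 0.15,
                "diabetes": 0.046,
                "cvd_history": 0.05,
                "atrial_fibrillation": 0.02,
                "lvh": 0.03,
                "family_history_stroke_or_mi": 0.15,
                "poor_diet": 0.50,
                "high_alcohol": 0.15,
                "low_physical_activity": 0.40,
                "stress": 0.20,
                "cognitive_problems": 0.02,
                "memory_problems": 0.05,
                "previous_tbi": 0.03,
            },
            target_event_rate=0.032,
        )
    elif name == "rotterdam-like":
        base = dict(
            age={"male": (69.0, 8.7), "female": (71.7, 10.2)},
            sbp={"male": (138.7, 21.8), "female": (140.0, 22.8)},
            bmi={"male": (25.6, 2.9), "female": (26.7, 3.7)},
            prevalences={
                "antihypertensive_treatment": 0.30,
                "diabetes": 0.066,
                "cvd_history": 0.12,
                "atrial_fibrillation": 0.05,
                "lvh": 0.04,
                "family_history_stroke_or_mi": 0.15,
                "poor_diet": 0.40,
                "high_alcohol": 0.15,
                "low_physical_activity": 0.35,
                "stress": 0.15,
                "cognitive_problems": 0.04,
                "memory_problems": 0.08,
                "previous_tbi": 0.02,
            },
            target_event_rate=0.084,
        )
    elif name == "arcos-like":
        # stroke-only register: every row is an event, observed within one year
        base = dict(
            age={"male": (68.8, 13.2), "female": (72.4, 15.7)},
            sbp={"male": (156.8, 30.1), "female": (157.3, 29.9)},
            whr={"male": (0.9, 0.1), "female": (0.9, 0.1)},
            waist={"male": (97.2, 15.9), "female": (99.3, 14.5)},
            prevalences={
                "antihypertensive_treatment": 0.40,
                "diabetes": 0.20,
                "cvd_history": 0.25,
                "atrial_fibrillation": 0.10,
                "lvh": 0.06,
                "family_history_stroke_or_mi": 0.20,
                "non_caucasian": 0.25,
                "poor_diet": 0.50,
                "high_alcohol": 0.15,
                "low_physical_activity": 0.45,
                "stress": 0.20,
                "previous_stroke_or_tia": 0.15,
                "cognitive_problems": 0.05,
                "memory_problems": 0.08,
                "previous_tbi": 0.04,
            },
            target_event_rate=1.0,
        )
    else:
        raise ConfigError(
            f"unknown preset {name!r}; available: russia-like, rotterdam-like, arcos-like"
        )
    base.update(overrides)
    return CohortSpec(name=name, n=n, seed=seed, **base)
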