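"""Cohort CSV and model-config JSON reading/writing.

Cohort CSV dialect: one header row, columns named exactly as the
risk-factor-profile fields plus ``follow_up_years`` and ``event``; booleans
as 0/1; missing optionals empty; ``sex`` as male/female; decimal point.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ConfigError, DataError, ProfileError
from ..risk_models import (
    CoefficientSet,
    ModelConfig,
    RiskFactorProfile,
    RiskometerDeltaConfig,
    BmiRule,
    WaistRule,
    WhrRule,
)
from ..synthetic_cohorts import Cohort

logger = logging.getLogger(__name__)

_BOOL_COLUMNS = (
    "antihypertensive_treatment", "diabetes", "cvd_history",
    "atrial_fibrillation", "lvh", "family_history_stroke_or_mi",
    "non_caucasian", "poor_diet", "high_alcohol", "low_physical_activity",
    "stress", "previous_stroke_or_tia", "cognitive_problems",
    "memory_problems", "previous_tbi",
)
_OPTIONAL_FLOAT_COLUMNS = ("whr", "bmi", "waist_circumference_cm")
_REQUIRED_COLUMNS = ("age", "sex", "sbp", "smoking") + _BOOL_COLUMNS
_OUTCOME_COLUMNS = ("follow_up_years", "event")
#: convenience column: converted to the high_alcohol flag with a >= 2 cut
_DRINKS_COLUMN = "drinks_per_day"

COHORT_COLUMNS = (
    ("age", "sex", "sbp", "smoking")
    + _BOOL_COLUMNS
    + _OPTIONAL_FLOAT_COLUMNS
    + ("ethnic_group",)
    + _OUTCOME_COLUMNS
)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort in the canonical CSV dialect (deterministic bytes)."""
    rows = []
    for profile, t, e in zip(cohort.profiles, cohort.follow_up_years, cohort.events):
        row = {
            "age": profile.age,
            "sex": profile.sex,
            "sbp": profile.sbp,
            "smoking": profile.smoking,
            "ethnic_group": profile.ethnic_group,
            "follow_up_years": float(t),
            "event": int(e),
        }
        for col in _BOOL_COLUMNS:
            row[col] = int(getattr(profile, col))
        for col in _OPTIONAL_FLOAT_COLUMNS:
            value = getattr(profile, col)
            row[col] = "" if value is None else value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path, on_invalid: str = "raise") -> Cohort:
    """Read and validate a cohort CSV.

    ``on_invalid='skip'`` drops malformed rows with a logged warning instead
    of raising; row numbers in messages are 1-based data rows.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"cohort file not found: {path}")
    if on_invalid not in ("raise", "skip"):
        raise DataError("on_invalid must be 'raise' or 'skip'")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in frame.columns if c not in COHORT_COLUMNS + (_DRINKS_COLUMN,)]
    if unknown:
        raise DataError(f"unknown column(s) in {path.name}: {unknown}")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns
               and not (c == "high_alcohol" and _DRINKS_COLUMN in frame.columns)]
    if missing:
        raise DataError(f"missing required column(s) in {path.name}: {missing}")
    if len(frame) == 0:
        raise DataError(f"{path.name} has no rows")
    if _DRINKS_COLUMN in frame.columns:
        logger.info(
            "deriving high_alcohol from %s using the 'two or more drinks/day' cut",
            _DRINKS_COLUMN,
        )

    profiles, times, events, keep = [], [], [], []
    failures = []
    for i, raw in enumerate(frame.to_dict("records")):
        try:
            profiles.append(_parse_row(raw))
            times.append(float(raw.get("follow_up_years", "") or "nan"))
            events.append(int(raw.get("event", "0") or 0))
            keep.append(i)
        except (ProfileError, ValueError) as exc:
            message = f"row {i + 1}: {exc}"
            if on_invalid == "raise":
                raise DataError(message) from exc
            failures.append(message)
            logger.warning("skipping %s", message)
    if not profiles:
        raise DataError(f"{path.name}: every row failed validation")
    times_arr = np.asarray(times, dtype=float)
    if np.isnan(times_arr).all():
        times_arr = np.full(len(profiles), 1.0)  # no follow-up recorded
    else:
        times_arr = np.where(np.isnan(times_arr), 1.0, times_arr)
    return Cohort(
        profiles=profiles,
        follow_up_years=times_arr,
        events=np.asarray(events, dtype=int),
        metadata={"source": str(path), "skipped_rows": failures},
    )


def _parse_bool(raw: str, column: str) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise ValueError(f"column {column!r}: expected 0/1, got {raw!r}")


def _parse_row(raw: dict) -> RiskFactorProfile:
    kwargs: dict = {
        "age": float(raw["age"]),
        "sex": raw["sex"],
        "sbp": float(raw["sbp"]),
        "smoking": raw["smoking"],
        "ethnic_group": raw.get("ethnic_group") or "other",
    }
    for col in _BOOL_COLUMNS:
        if col == "high_alcohol" and col not in raw and _DRINKS_COLUMN in raw:
            kwargs[col] = float(raw[_DRINKS_COLUMN]) >= 2.0
        else:
            kwargs[col] = _parse_bool(raw.get(col, "0") or "0", col)
    for col in _OPTIONAL_FLOAT_COLUMNS:
        value = raw.get(col, "")
        kwargs[col] = float(value) if value not in ("", None) else None
    return RiskFactorProfile(**kwargs)


# ---------------------------------------------------------------------------
# model config JSON
# ---------------------------------------------------------------------------

_COEFF_KEYS = {"betas", "covariate_means", "baseline_survival", "reference_sbp", "provenance"}
_DELTA_KEYS = {"lp_deltas", "rr_multipliers", "prior_stroke_percent_points",
               "whr_rule", "bmi_rule", "waist_rule"}
_TOP_KEYS = {"model_name", "sex_specific", "deltas"}


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) at {where}: {unknown}")


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and schema-validate a model config JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"model config not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path.name} is not valid JSON: {exc}") from exc
    config = parse_model_config(raw)
    logger.info("loaded model config %s (sha256 %s)", path.name, config_hash_text(text))
    return config


def parse_model_config(raw: dict) -> ModelConfig:
    if not isinstance(raw, dict):
        raise ConfigError("model config must be a JSON object")
    _reject_unknown(raw, _TOP_KEYS, "/")
    if "model_name" not in raw or "sex_specific" not in raw:
        raise ConfigError("model config requires 'model_name' and 'sex_specific'")
    by_sex = {}
    for sex, section in raw["sex_specific"].items():
        _reject_unknown(section, _COEFF_KEYS, f"/sex_specific/{sex}")
        survival = {int(k): float(v) for k, v in section.get("baseline_survival", {}).items()}
        if 5 not in survival and 10 in survival:
            logger.info(
                "S0(5) absent for sex=%s; will derive from S0(10) under a "
                "constant baseline hazard", sex,
            )
        by_sex[sex] = CoefficientSet(
            sex=sex,
            betas={k: float(v) for k, v in section.get("betas", {}).items()},
            covariate_means={k: float(v) for k, v in section.get("covariate_means", {}).items()},
            baseline_survival=survival,
            reference_sbp=float(section.get("reference_sbp", 120.0)),
            provenance=str(section.get("provenance", "")),
        )
    deltas = _parse_deltas(raw.get("deltas", {}))
    return ModelConfig(model_name=str(raw["model_name"]), by_sex=by_sex, deltas=deltas)


def _parse_deltas(raw: dict) -> RiskometerDeltaConfig:
    _reject_unknown(raw, _DELTA_KEYS, "/deltas")
    kwargs: dict = {}
    if "lp_deltas" in raw:
        defaults = RiskometerDeltaConfig().lp_deltas
        kwargs["lp_deltas"] = {**defaults, **{k: float(v) for k, v in raw["lp_deltas"].items()}}
    if "rr_multipliers" in raw:
        defaults = RiskometerDeltaConfig().rr_multipliers
        kwargs["rr_multipliers"] = {
            **defaults, **{k: float(v) for k, v in raw["rr_multipliers"].items()}
        }
    if "prior_stroke_percent_points" in raw:
        kwargs["prior_stroke_percent_points"] = {
            int(k): float(v) for k, v in raw["prior_stroke_percent_points"].items()
        }
    for rule_key, rule_cls in (("whr_rule", WhrRule), ("bmi_rule", BmiRule),
                               ("waist_rule", WaistRule)):
        if rule_key in raw:
            try:
                kwargs[rule_key] = rule_cls(**raw[rule_key])
            except TypeError as exc:
                raise ConfigError(f"invalid /deltas/{rule_key}: {exc}") from exc
    return RiskometerDeltaConfig(**kwargs)


def load_default_model_config() -> ModelConfig:
    """The packaged default model config (see ``strokerisk/data``)."""
    text = resources.files("strokerisk.data").joinpath("default_model.json").read_text()
    return parse_model_config(json.loads(text))


def config_hash_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def config_hash(config: ModelConfig) -> str:
    """Stable short hash of a parsed model config."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, float) and math.isnan(obj):
            return "nan"
        return obj

    from dataclasses import asdict
    payload = json.dumps(_clean(asdict(config)), sort_keys=True)
    return config_hash_text(payload)
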