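"""Validation-report orchestration and deterministic JSON serialization."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from typing import Mapping, Sequence

import numpy as np

from .. import calibration_classification as cc
from .. import discrimination as disc
from ..errors import ConfigError, DataError
from ..risk_models import ModelConfig, score_cohort
from ..synthetic_cohorts import Cohort
from .io import config_hash

logger = logging.getLogger(__name__)

ACCURACY_TARGETS = (50.0, 70.0, 80.0, 85.0, 90.0)


def run_validation(
    cohort: Cohort,
    models: Mapping[str, ModelConfig],
    horizons: Sequence[int] = (5,),
    pooled: bool = False,
    g: int = 10,
    accuracy_targets: Sequence[float] = ACCURACY_TARGETS,
    thresholds: Mapping | None = None,
    reference_model: str | None = None,
) -> dict:
    """Score every model and compute the full statistics battery.

    Results are stratified by sex by default (``pooled=True`` adds a pooled
    stratum instead). Strata without both outcome classes have their ROC
    cells marked unavailable but the run continues. The report is a plain
    nested dict, deterministic for fixed inputs, serializable with
    :func:`report_to_json`.
    """
    if not models:
        raise ConfigError("at least one model is required")
    model_names = list(models)
    reference = reference_model or model_names[0]
    if reference not in models:
        raise ConfigError(f"reference model {reference!r} not among models {model_names}")

    sexes = np.array([p.sex for p in cohort.profiles])
    strata = {"pooled": np.ones(len(cohort), dtype=bool)} if pooled else {
        "male": sexes == "male", "female": sexes == "female",
    }

    report: dict = {
        "metadata": {
            "n": len(cohort),
            "cohort": cohort.metadata,
            "config_hashes": {name: config_hash(cfg) for name, cfg in models.items()},
            "models": model_names,
            "horizons": [int(h) for h in horizons],
            "reference_model": reference,
        },
        "results": {},
    }

    scored: dict[tuple[str, int], np.ndarray] = {}
    for name, config in models.items():
        for horizon in horizons:
            scored[(name, horizon)] = score_cohort(
                cohort.profiles, config, horizon, model=_model_kind(name, config)
            ).risks_percent

    for stratum, mask in strata.items():
        if mask.sum() == 0:
            report["results"][stratum] = {"unavailable": "stratum is empty"}
            continue
        events = cohort.events[mask]
        times = cohort.follow_up_years[mask]
        stratum_report: dict = {}
        for name in model_names:
            for horizon in horizons:
                risks = scored[(name, horizon)][mask]
                key = f"{name}/{horizon}y"
                stratum_report[key] = _evaluate_one(
                    name, stratum, horizon, risks, events, times,
                    g, accuracy_targets, thresholds,
                )
                if name != reference:
                    ref_risks = scored[(reference, horizon)][mask]
                    stratum_report[key]["delong_vs_reference"] = _paired_delong(
                        risks, ref_risks, events
                    )
                    stratum_report[key]["crosstab_vs_reference"] = _crosstab(
                        name, reference, stratum, horizon, risks, ref_risks, thresholds
                    )
        report["results"][stratum] = stratum_report
    return report


def _model_kind(name: str, config: ModelConfig) -> str:
    # scoring route: 'fsrs' scores the base model, anything else the extended
    return "fsrs" if name == "fsrs" else "riskometer"


def _evaluate_one(name, stratum, horizon, risks, events, times,
                  g, accuracy_targets, thresholds) -> dict:
    out: dict = {"mean_risk_percent": float(np.mean(risks))}
    fractions = risks / 100.0
    try:
        data = disc.ScoredOutcomes(scores=risks, events=events, times=times)
        roc = disc.delong_ci(data)
        out["roc"] = {
            "auroc": roc.auroc, "ci_low": roc.ci_low,
            "ci_high": roc.ci_high, "level": roc.level,
        }
        conc = disc.harrell_c(data)
        out["concordance"] = asdict(conc)
        out["pseudo_r2_percent"] = disc.pseudo_r2(fractions, events)
    except DataError as exc:
        out["roc"] = {"unavailable": str(exc)}
        logger.warning("%s/%s/%sy: discrimination unavailable: %s",
                       name, stratum, horizon, exc)
    try:
        hl = cc.hosmer_lemeshow(fractions, events, g=g, on_degenerate="merge")
        out["hosmer_lemeshow"] = {
            "chi2": hl.hl_chi2, "df": hl.df, "p_value": hl.p_value,
            "groups": [asdict(grp) for grp in hl.groups],
        }
    except DataError as exc:
        out["hosmer_lemeshow"] = {"unavailable": str(exc)}
    out["threshold_performance"] = []
    for target in accuracy_targets:
        try:
            perf = cc.threshold_for_accuracy(risks, events, target)
            out["threshold_performance"].append(asdict(perf))
        except DataError as exc:
            out["threshold_performance"].append(
                {"accuracy_target": target, "unavailable": str(exc)}
            )
    return out


def _classification_threshold(name, stratum, horizon, thresholds) -> float | None:
    table = thresholds if thresholds is not None else cc.default_thresholds()
    try:
        return float(table[name][stratum][str(horizon)])
    except (KeyError, TypeError):
        return None


def _crosstab(name, reference, stratum, horizon, risks, ref_risks, thresholds):
    thr_a = _classification_threshold(name, stratum, horizon, thresholds)
    thr_b = _classification_threshold(reference, stratum, horizon, thresholds)
    if thr_a is None or thr_b is None:
        return {"unavailable": "no classification threshold configured for this stratum"}
    tab = cc.cross_tabulate(
        cc.classify_high_low(risks, thr_a),
        cc.classify_high_low(ref_risks, thr_b),
    )
    return {"threshold": thr_a, "reference_threshold": thr_b,
            "n": tab.n, "counts": tab.counts, "percents": tab.percents}


def _paired_delong(risks, ref_risks, events):
    try:
        return disc.delong_paired_test(
            disc.ScoredOutcomes(scores=risks, events=events),
            disc.ScoredOutcomes(scores=ref_risks, events=events),
        )
    except DataError as exc:
        return {"unavailable": str(exc)}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int = 12):
    """Round every float to ``sig`` significant digits for stable output."""
    if isinstance(obj, float):
        if obj != obj or obj in (float("inf"), float("-inf")):
            return repr(obj)
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, np.floating):
        return _round_floats(float(obj), sig)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if is_dataclass(obj) and not isinstance(obj, type):
        return _round_floats(asdict(obj), sig)
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic JSON (floats at 12 significant digits, sorted keys)."""
    return json.dumps(_round_floats(report), sort_keys=True, indent=2)
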