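"""Calibration (Hosmer-Lemeshow, deciles of predicted risk) and
threshold-based classification (accuracy-targeted thresholds,
sensitivity/specificity, high/low cross-tabulation between models).

Conventions, chosen once and used everywhere:

* quantile grouping assigns tied predictions to the lower group, so groups
  may be unequal in size;
* classification is "high" iff predicted risk >= threshold (boundary counts
  as high).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError

_THRESHOLDS_RESOURCE = "classification_thresholds.json"


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationGroup:
    group: int
    n: int
    mean_predicted_percent: float
    observed_events: int
    observed_rate_percent: float


@dataclass(frozen=True)
class CalibrationTable:
    groups: tuple[CalibrationGroup, ...]
    hl_chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ThresholdPerformance:
    threshold: float
    accuracy_target: float
    n_high: int
    pct_high: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass(frozen=True)
class CrossTab:
    """2x2 high/low agreement between two models; cell names are <A>_<B>."""

    n: int
    counts: dict[str, int]
    percents: dict[str, float]


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def _validate_pred(pred_risks: np.ndarray) -> np.ndarray:
    p = np.asarray(pred_risks, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DataError("pred_risks must be a non-empty 1-d vector")
    if (p < 0).any() or (p > 1).any():
        raise DataError("pred_risks must be risk fractions in [0, 1]")
    return p


def quantile_groups(pred_risks: np.ndarray, g: int) -> np.ndarray:
    """Group index in [0, g) per subject by quantiles of predicted risk.

    Ties are assigned to the lower group (all equal values share the group of
    their first sorted occurrence), so some groups may be empty.
    """
    p = np.asarray(pred_risks, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    base = (np.arange(n) * g) // n
    first_occurrence = np.searchsorted(sorted_p, sorted_p, side="left")
    merged = base[first_occurrence]
    groups = np.empty(n, dtype=int)
    groups[order] = merged
    return groups


def _group_table(p: np.ndarray, y: np.ndarray, g: int) -> list[CalibrationGroup]:
    groups = quantile_groups(p, g)
    table = []
    for k in range(g):
        mask = groups == k
        n_k = int(mask.sum())
        if n_k == 0:
            continue
        observed = int(y[mask].sum())
        table.append(
            CalibrationGroup(
                group=k,
                n=n_k,
                mean_predicted_percent=100.0 * float(p[mask].mean()),
                observed_events=observed,
                observed_rate_percent=100.0 * observed / n_k,
            )
        )
    return table


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def hosmer_lemeshow(
    pred_risks: np.ndarray,
    events: np.ndarray,
    g: int = 10,
    on_degenerate: str = "error",
    df_policy: str = "fitted",
) -> CalibrationTable:
    """Hosmer-Lemeshow goodness-of-fit over g quantile groups of risk.

    chi2 = sum over groups of (O-E)^2/E + (O'-E')^2/E' with E the sum of
    predicted risks in the group. ``df_policy='fitted'`` uses the classical
    df = groups - 2 (appropriate when the probabilities come from a model
    fitted to these data); ``'external'`` uses df = groups, the correct
    reference when the probabilities are externally specified, as in
    validating a fixed published algorithm. ``on_degenerate='merge'`` folds
    a group whose expected events (or non-events) are zero into its
    neighbour instead of raising.
    """
    p = _validate_pred(pred_risks)
    y = np.asarray(events, dtype=int)
    if len(y) != len(p):
        raise DataError("events must align with pred_risks")
    if len(p) < 2 * g:
        raise DataError(f"need at least {2 * g} subjects for g={g} groups, got {len(p)}")
    if on_degenerate not in ("error", "merge"):
        raise DataError("on_degenerate must be 'error' or 'merge'")
    if df_policy not in ("fitted", "external"):
        raise DataError("df_policy must be 'fitted' or 'external'")

    table = _group_table(p, y, g)
    # expected events per group from the predictions themselves
    cells = []
    for grp in table:
        e_events = grp.n * grp.mean_predicted_percent / 100.0
        cells.append([grp.n, grp.observed_events, e_events])
    if on_degenerate == "merge":
        merged = [cells[0]]
        for n_k, o_k, e_k in cells[1:]:
            prev = merged[-1]
            if e_k <= 0 or (prev[0] - prev[2]) <= 0 or prev[2] <= 0 or (n_k - e_k) <= 0:
                prev[0] += n_k
                prev[1] += o_k
                prev[2] += e_k
            else:
                merged.append([n_k, o_k, e_k])
        cells = merged
    chi2 = 0.0
    for n_k, o_k, e_k in cells:
        e_non = n_k - e_k
        if e_k <= 0 or e_non <= 0:
            raise DataError(
                f"a group has zero expected events or non-events (n={n_k}, E={e_k}); "
                "use on_degenerate='merge' to fold sparse groups"
            )
        chi2 += (o_k - e_k) ** 2 / e_k + ((n_k - o_k) - e_non) ** 2 / e_non
    df = len(cells) - 2 if df_policy == "fitted" else len(cells)
    if df < 1:
        raise DataError(f"too few groups after merging ({len(cells)}) for a chi2 test")
    p_value = float(stats.chi2.sf(chi2, df))
    return CalibrationTable(groups=tuple(table), hl_chi2=float(chi2), df=df, p_value=p_value)


def calibration_by_decile(
    pred_risks: np.ndarray, events: np.ndarray, g: int = 10
) -> list[tuple[float, float]]:
    """(mean predicted %, observed event rate %) per quantile group of risk."""
    p = _validate_pred(pred_risks)
    y = np.asarray(events, dtype=int)
    if len(y) != len(p):
        raise DataError("events must align with pred_risks")
    if len(p) < g:
        raise DataError(f"need at least {g} subjects, got {len(p)}")
    table = _group_table(p, y, g)
    return [(grp.mean_predicted_percent, grp.observed_rate_percent) for grp in table]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def confusion_at_threshold(
    pred_risks: np.ndarray,
    events: np.ndarray,
    threshold: float,
    accuracy_target: float = float("nan"),
) -> ThresholdPerformance:
    """Sensitivity/specificity/accuracy (all in %) at ``pred >= threshold``."""
    p = np.asarray(pred_risks, dtype=float)
    y = np.asarray(events, dtype=int)
    if len(p) == 0 or len(y) != len(p):
        raise DataError("pred_risks and events must be equal-length non-empty vectors")
    high = p >= threshold
    tp = int((high & (y == 1)).sum())
    fp = int((high & (y == 0)).sum())
    fn = int((~high & (y == 1)).sum())
    tn = int((~high & (y == 0)).sum())
    n = len(p)
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else 0.0
    return ThresholdPerformance(
        threshold=float(threshold),
        accuracy_target=accuracy_target,
        n_high=tp + fp,
        pct_high=100.0 * (tp + fp) / n,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=100.0 * (tp + tn) / n,
    )


def threshold_for_accuracy(
    pred_risks: np.ndarray,
    events: np.ndarray,
    target_accuracy: float,
    mode: str = "lowest",
) -> ThresholdPerformance:
    """Scan all distinct score cut-points for the accuracy target.

    ``mode='lowest'`` (default) returns the lowest threshold whose accuracy
    reaches the target — i.e. maximal sensitivity subject to the accuracy
    constraint. ``mode='closest'`` returns the threshold whose accuracy is
    nearest the target.
    """
    if mode not in ("lowest", "closest"):
        raise DataError("mode must be 'lowest' or 'closest'")
    p = np.asarray(pred_risks, dtype=float)
    candidates = np.unique(p)
    results = [
        confusion_at_threshold(p, events, thr, accuracy_target=target_accuracy)
        for thr in candidates
    ]
    if mode == "closest":
        return min(results, key=lambda r: (abs(r.accuracy - target_accuracy), r.threshold))
    feasible = [r for r in results if r.accuracy >= target_accuracy]
    if not feasible:
        best = max(r.accuracy for r in results)
        raise DataError(
            f"no threshold reaches {target_accuracy}% accuracy "
            f"(maximum achievable: {best:.2f}%)"
        )
    return min(feasible, key=lambda r: r.threshold)


def classify_high_low(pred_risks: np.ndarray, threshold: float) -> np.ndarray:
    """Label vector 'high'/'low' with high iff pred >= threshold."""
    p = np.asarray(pred_risks, dtype=float)
    return np.where(p >= threshold, "high", "low")


def default_thresholds() -> dict:
    """Shipped high/low classification thresholds per model, sex and horizon
    (risk %), selected for 80% accuracy with >80% specificity."""
    text = resources.files("strokerisk.data").joinpath(_THRESHOLDS_RESOURCE).read_text()
    return json.loads(text)


def default_threshold(model: str, sex: str, horizon: int) -> float:
    table = default_thresholds()
    try:
        return float(table[model][sex][str(horizon)])
    except KeyError:
        raise ConfigError(
            f"no shipped threshold for model={model!r}, sex={sex!r}, horizon={horizon}"
        ) from None


def cross_tabulate(labels_a: np.ndarray, labels_b: np.ndarray) -> CrossTab:
    """2x2 cross-tabulation of two models' high/low labels."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise DataError("label vectors must have equal length")
    if len(a) == 0:
        raise DataError("label vectors must be non-empty")
    n = len(a)
    counts = {}
    for la in ("low", "high"):
        for lb in ("low", "high"):
            counts[f"{la}_{lb}"] = int(((a == la) & (b == lb)).sum())
    if sum(counts.values()) != n:
        raise DataError("labels must be 'high' or 'low'")
    percents = {k: 100.0 * v / n for k, v in counts.items()}
    return CrossTab(n=n, counts=counts, percents=percents)
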