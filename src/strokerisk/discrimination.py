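"""Discrimination statistics: ROC/AUROC with DeLong inference, Harrell's C,
Somers' D and pseudo-R².

Tie handling is uniform across the module: tied scores earn 0.5 credit, both
in the Mann-Whitney AUROC estimator and in concordance over comparable
survival pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError

_PROB_CLIP = 1e-12  # likelihood computations clip probabilities to [clip, 1-clip]


@dataclass(frozen=True)
class ScoredOutcomes:
    """Predicted scores with binary outcomes and optional follow-up times."""

    scores: np.ndarray
    events: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        events = np.asarray(self.events)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "events", events.astype(int))
        if scores.ndim != 1 or events.ndim != 1 or len(scores) != len(events):
            raise DataError("scores and events must be equal-length 1-d vectors")
        if not np.isin(self.events, (0, 1)).all():
            raise DataError("events must be 0/1 indicators")
        if self.times is not None:
            times = np.asarray(self.times, dtype=float)
            object.__setattr__(self, "times", times)
            if len(times) != len(scores):
                raise DataError("times must align with scores")
            if (times < 0).any():
                raise DataError("follow-up times must be >= 0")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class RocSummary:
    auroc: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    curve: tuple[tuple[float, float, float], ...] = ()


@dataclass(frozen=True)
class ConcordanceSummary:
    c_statistic: float
    somers_d: float
    n_comparable_pairs: int


def _split(data: ScoredOutcomes, min_events: int = 1, min_nonevents: int = 1):
    pos = data.scores[data.events == 1]
    neg = data.scores[data.events == 0]
    if len(pos) < min_events:
        raise DataError(
            f"need at least {min_events} event(s), got {len(pos)}: "
            "the event class is absent or too small"
        )
    if len(neg) < min_nonevents:
        raise DataError(
            f"need at least {min_nonevents} non-event(s), got {len(neg)}: "
            "the non-event class is absent or too small"
        )
    return pos, neg


# ---------------------------------------------------------------------------
# ROC curve and AUROC
# ---------------------------------------------------------------------------

def roc_curve(data: ScoredOutcomes) -> tuple[tuple[float, float, float], ...]:
    """(FPR, TPR, threshold) points, one per distinct threshold, plus (0,0,inf).

    A point's threshold t means "positive iff score >= t"; scores are swept
    in descending order and tied scores share a point.
    """
    pos, neg = _split(data)
    m, n = len(pos), len(neg)
    order = np.argsort(-data.scores, kind="stable")
    sorted_scores = data.scores[order]
    sorted_events = data.events[order]
    # last index of each run of tied scores
    distinct_end = np.nonzero(np.diff(sorted_scores) != 0)[0]
    ends = np.concatenate([distinct_end, [len(sorted_scores) - 1]])
    tp = np.cumsum(sorted_events)[ends]
    fp = np.cumsum(1 - sorted_events)[ends]
    points = [(0.0, 0.0, float("inf"))]
    for end, tp_k, fp_k in zip(ends, tp, fp):
        points.append((fp_k / n, tp_k / m, float(sorted_scores[end])))
    return tuple(points)


def _pair_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """ψ(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise; events × non-events."""
    diff = pos[:, None] - neg[None, :]
    return (diff > 0).astype(float) + 0.5 * (diff == 0)


def auroc(data: ScoredOutcomes) -> float:
    """Mann-Whitney AUROC: mean pairwise ψ over (event, non-event) pairs."""
    pos, neg = _split(data)
    return float(_pair_matrix(pos, neg).mean())


def trapezoid_auroc(curve: tuple[tuple[float, float, float], ...]) -> float:
    """Trapezoidal area under an ROC curve (equals the pair estimator)."""
    fpr = np.array([p[0] for p in curve])
    tpr = np.array([p[1] for p in curve])
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# DeLong variance, CI and paired test
# ---------------------------------------------------------------------------

def _delong_components(data: ScoredOutcomes):
    """AUROC plus the per-subject structural components V10 (events) and V01."""
    pos, neg = _split(data, min_events=2, min_nonevents=2)
    psi = _pair_matrix(pos, neg)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_variance(data: ScoredOutcomes) -> float:
    theta, v10, v01 = _delong_components(data)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_ci(data: ScoredOutcomes, level: float = 0.95) -> RocSummary:
    """AUROC with a normal-approximation DeLong CI, truncated to [0, 1]."""
    if not (0 < level < 1):
        raise DataError(f"confidence level must be in (0, 1), got {level}")
    theta, v10, v01 = _delong_components(data)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return RocSummary(
        auroc=theta,
        ci_low=float(max(0.0, theta - half)),
        ci_high=float(min(1.0, theta + half)),
        level=level,
        curve=roc_curve(data),
    )


def delong_paired_test(data_a: ScoredOutcomes, data_b: ScoredOutcomes) -> dict[str, float]:
    """Two-sided DeLong test for two correlated AUROCs on the same subjects."""
    if len(data_a) != len(data_b):
        raise DataError("paired test requires equal-length score vectors")
    if not np.array_equal(data_a.events, data_b.events):
        raise DataError("paired test requires identical event vectors")
    theta_a, v10_a, v01_a = _delong_components(data_a)
    theta_b, v10_b, v01_b = _delong_components(data_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = theta_a - theta_b
    if abs(diff) < 1e-15:
        return {"z": 0.0, "p_two_sided": 1.0, "auroc_a": theta_a, "auroc_b": theta_b}
    if var_diff <= 0:
        z_stat = float("inf") if diff > 0 else float("-inf")
        return {"z": z_stat, "p_two_sided": 0.0, "auroc_a": theta_a, "auroc_b": theta_b}
    z_stat = diff / float(np.sqrt(var_diff))
    p = 2 * stats.norm.sf(abs(z_stat))
    return {"z": float(z_stat), "p_two_sided": float(p),
            "auroc_a": theta_a, "auroc_b": theta_b}


# ---------------------------------------------------------------------------
# Harrell's C / Somers' D
# ---------------------------------------------------------------------------

def harrell_c(data: ScoredOutcomes, tied_event_times: str = "exclude") -> ConcordanceSummary:
    """Concordance over comparable (possibly censored) time-to-event pairs.

    A pair is comparable when the subject with the earlier time had an event
    (so their relative ordering is known). Higher scores should go with
    earlier events; tied scores earn 0.5. Pairs of events at exactly the
    same time are excluded by default (``tied_event_times='half'`` scores
    them 0.5).
    """
    if data.times is None:
        raise DataError("harrell_c requires follow-up times")
    if tied_event_times not in ("exclude", "half"):
        raise DataError("tied_event_times must be 'exclude' or 'half'")
    t = data.times
    e = data.events.astype(bool)
    s = data.scores
    # case i (event) vs subject j with t_i < t_j: comparable
    earlier = t[:, None] < t[None, :]
    comparable = e[:, None] & earlier
    # event vs non-event at exactly the same time: the censored subject is
    # known to have outlived the case
    same_time = t[:, None] == t[None, :]
    comparable |= e[:, None] & ~e[None, :] & same_time
    score_diff = s[:, None] - s[None, :]
    concordant = comparable & (score_diff > 0)
    tied_score = comparable & (score_diff == 0)
    n_pairs = int(comparable.sum())
    credit = concordant.sum() + 0.5 * tied_score.sum()
    if tied_event_times == "half":
        both_events_tied = e[:, None] & e[None, :] & same_time
        np.fill_diagonal(both_events_tied, False)
        extra = int(both_events_tied.sum()) // 2  # unordered pairs
        n_pairs += extra
        credit += 0.5 * extra
    if n_pairs == 0:
        raise DataError("no comparable pairs (no events, or all times tied)")
    c = float(credit / n_pairs)
    return ConcordanceSummary(c_statistic=c, somers_d=2 * c - 1, n_comparable_pairs=n_pairs)


# ---------------------------------------------------------------------------
# pseudo-R²
# ---------------------------------------------------------------------------

def pseudo_r2(
    pred_risks: np.ndarray, events: np.ndarray, variant: str = "nagelkerke"
) -> float:
    """Likelihood-based R² (percent) of predicted risk fractions vs outcomes.

    Compares the Bernoulli log-likelihood under the predictions with the
    null model at the observed prevalence; no refitting. Cox-Snell
    ``1 - exp(2(L0 - L1)/n)``, Nagelkerke rescales by its maximum.
    """
    if variant not in ("nagelkerke", "coxsnell"):
        raise DataError("variant must be 'nagelkerke' or 'coxsnell'")
    p = np.clip(np.asarray(pred_risks, dtype=float), _PROB_CLIP, 1 - _PROB_CLIP)
    y = np.asarray(events, dtype=float)
    n = len(p)
    if n == 0 or len(y) != n:
        raise DataError("pred_risks and events must be equal-length non-empty vectors")
    l1 = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    prev = np.clip(y.mean(), _PROB_CLIP, 1 - _PROB_CLIP)
    l0 = float(np.sum(y * np.log(prev) + (1 - y) * np.log(1 - prev)))
    cox_snell = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    if variant == "coxsnell":
        return 100.0 * float(cox_snell)
    max_cs = 1.0 - np.exp(2.0 * l0 / n)
    return 100.0 * float(cox_snell / max_cs)
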