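"""Reader-study evaluation statistics.

Implements the evaluation toolkit used to compare an AI score against
radiologists' BI-RADS assessments at breast level: ordinal recoding of
BI-RADS into a 6-point suspicion index, AUROC / AUPRC, operating points
matched to a comparator's sensitivity or specificity (with PPV2, NPV and
biopsy rate), reader-AI hybrid fusion of standardized scores, percentile
bootstrap confidence intervals, a one-tailed paired permutation (swap)
test, triage operating points, and subgroup evaluation.

Conventions: a breast is called positive when its score is >= the decision
threshold; PPV here is PPV2 = cancers among biopsied / biopsies recommended;
biopsy rate = (TP + FP) / N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

# BI-RADS 1 and 2 collapse into the lowest level of suspicion; 3, 4A, 4B,
# 4C, 5 are increasing levels. 0 and 6 are not permitted reader outputs.
SUSPICION_INDEX = {"1": 0, "2": 0, "3": 1, "4A": 2, "4B": 3, "4C": 4, "5": 5}
POSITIVE_BIRADS = frozenset({"4A", "4B", "4C", "5"})


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float  # PPV2; nan when no breast is called positive
    npv: float  # nan when no breast is called negative
    biopsy_rate: float


@dataclass(frozen=True)
class CIResult:
    point: float
    lower95: float
    upper95: float
    n_boot: int


@dataclass(frozen=True)
class HybridConfig:
    fusion_weight: float = 0.5  # weight on the expert; 1 - weight on the AI

    def __post_init__(self):
        if not 0.0 <= self.fusion_weight <= 1.0:
            raise ValueError(f"fusion_weight must be in [0, 1], got {self.fusion_weight}")


def birads_to_ordinal(score: str | int) -> int:
    """BI-RADS -> 6-point suspicion index (1 and 2 collapse to 0)."""
    key = str(score)
    if key not in SUSPICION_INDEX:
        raise ValueError(
            f"BI-RADS {score!r} has no suspicion index (0 and 6 are not permitted)"
        )
    return SUSPICION_INDEX[key]


def dichotomize_birads(score: str | int) -> int:
    """1 for a biopsy recommendation (BI-RADS >= 4A), else 0."""
    key = str(score)
    if key not in SUSPICION_INDEX:
        raise ValueError(f"cannot dichotomize BI-RADS {score!r}")
    return int(key in POSITIVE_BIRADS)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative (ties half).

    Computed from the rank statistic; identical to pairwise enumeration.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision (step-wise integral of precision over recall)."""
    labels = _check_binary(np.asarray(labels))
    if labels.sum() == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def _confusion_at(scores: np.ndarray, labels: np.ndarray, thr: float):
    pos = scores >= thr
    tp = int((pos & (labels == 1)).sum())
    fp = int((pos & (labels == 0)).sum())
    fn = int((~pos & (labels == 1)).sum())
    tn = int((~pos & (labels == 0)).sum())
    return tp, fp, fn, tn


def _point_at(scores: np.ndarray, labels: np.ndarray, thr: float) -> OperatingPoint:
    tp, fp, fn, tn = _confusion_at(scores, labels, thr)
    n = len(scores)
    return OperatingPoint(
        threshold=float(thr),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        biopsy_rate=(tp + fp) / n,
    )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    return np.concatenate([uniq, [uniq[-1] + 1.0]])  # last: nothing positive


def operating_point_at(
    scores: Sequence[float],
    labels: Sequence[int],
    target: float,
    match: Literal["sensitivity", "specificity"],
) -> OperatingPoint:
    """Operating point matched to a comparator's sensitivity or specificity.

    Chooses the threshold whose matched rate is the smallest achievable
    value >= target (no interpolation); exact ties prefer the threshold
    maximizing the complementary rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target must be in [0, 1], got {target}")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("operating_point_at requires both classes present")
    if match not in ("sensitivity", "specificity"):
        raise ValueError(f"match must be 'sensitivity' or 'specificity', got {match!r}")
    points = [_point_at(scores, labels, thr) for thr in _candidate_thresholds(scores)]
    matched = np.array([getattr(p, match) for p in points])
    other_name = "specificity" if match == "sensitivity" else "sensitivity"
    feasible = matched >= target - 1e-12
    if not feasible.any():
        raise ValueError(
            f"target {match} {target} unreachable; best achievable is {matched.max():.6f}"
        )
    best_rate = matched[feasible].min()
    tied = [
        p for p, m, f in zip(points, matched, feasible) if f and m == best_rate
    ]
    return max(tied, key=lambda p: getattr(p, other_name))


def hybrid_scores(
    reader_scores: Sequence[float],
    ai_scores: Sequence[float],
    config: HybridConfig = HybridConfig(),
) -> np.ndarray:
    """Fuse standardized reader and AI scores with a fixed weight.

    Each input is standardized to zero mean and unit variance over the
    table; zero-variance inputs standardize to all zeros with a warning.
    """
    r = np.asarray(reader_scores, dtype=float)
    a = np.asarray(ai_scores, dtype=float)
    if r.shape != a.shape or r.size < 2:
        raise ValueError("reader and AI score vectors must share a length >= 2")

    def standardize(x: np.ndarray, name: str) -> np.ndarray:
        sd = x.std()
        if sd == 0:
            warnings.warn(f"{name} scores have zero variance; standardized to zeros")
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    lam = config.fusion_weight
    return lam * standardize(r, "reader") + (1.0 - lam) * standardize(a, "AI")


def bootstrap_ci(
    metric_fn: Callable[[pd.DataFrame], float],
    table: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> CIResult:
    """Percentile 95% CI over breast-level resamples with replacement.

    Resamples on which the metric is undefined (e.g. single-class) are
    redrawn; if more than half of all draws fail the metric is considered
    undefined on this table and an error is raised.
    """
    rng = rng or np.random.default_rng(0)
    n = len(table)
    point = float(metric_fn(table))
    values = []
    failures = 0
    attempts = 0
    while len(values) < n_boot:
        attempts += 1
        if attempts > 4 * n_boot and failures / attempts > 0.5:
            raise ValueError("metric undefined on most bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        sample = table.iloc[idx]
        try:
            values.append(float(metric_fn(sample)))
        except ValueError:
            failures += 1
            continue
    lo, hi = np.percentile(values, [2.5, 97.5])
    return CIResult(point=point, lower95=float(lo), upper95=float(hi), n_boot=n_boot)


def permutation_test(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    labels: Sequence[int],
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_trials: int = 10000,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided paired permutation (swap) test that model a exceeds model b.

    The observed statistic is metric(a) - metric(b); each trial swaps a_i
    and b_i independently with probability 1/2 and recomputes the
    difference. The p-value uses add-one smoothing, so it lies in (0, 1].
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = rng or np.random.default_rng(0)
    labels = _check_binary(np.asarray(labels))
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("labels, scores_a and scores_b must share one length")
    observed = metric_fn(a, labels) - metric_fn(b, labels)
    exceed = 0
    for _ in range(n_trials):
        mask = rng.random(a.size) < 0.5
        a2 = np.where(mask, b, a)
        b2 = np.where(mask, a, b)
        null = metric_fn(a2, labels) - metric_fn(b2, labels)
        if null >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_trials)


def triage_points(
    scores: Sequence[float],
    labels: Sequence[int],
    mode: Literal["dismiss", "escalate"],
    target: float,
) -> OperatingPoint:
    """Extreme operating points for triage work streams.

    ``dismiss``: highest threshold keeping NPV >= target (maximizes the
    fraction of low-risk breasts auto-dismissed; report its specificity).
    ``escalate``: lowest threshold keeping PPV >= target (maximizes the
    fraction of cancers fast-tracked; report its sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("triage_points requires both classes present")
    points = [_point_at(scores, labels, thr) for thr in _candidate_thresholds(scores)]
    if mode == "dismiss":
        feasible = [
            p for p in points if not np.isnan(p.npv) and p.npv >= target - 1e-12
        ]
        if not feasible:
            best = np.nanmax([p.npv for p in points])
            raise ValueError(f"NPV target {target} unreachable; best achievable {best:.6f}")
        return max(feasible, key=lambda p: p.threshold)
    if mode == "escalate":
        feasible = [
            p for p in points if not np.isnan(p.ppv) and p.ppv >= target - 1e-12
        ]
        if not feasible:
            best = np.nanmax([p.ppv for p in points])
            raise ValueError(f"PPV target {target} unreachable; best achievable {best:.6f}")
        return min(feasible, key=lambda p: p.threshold)
    raise ValueError(f"mode must be 'dismiss' or 'escalate', got {mode!r}")


def subgroup_eval(
    table: pd.DataFrame,
    group_column: str,
    metric_fn: Callable[[pd.DataFrame], float],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, CIResult | None]:
    """Metric + bootstrap CI per subgroup; single-class groups map to None."""
    if group_column not in table.columns:
        raise ValueError(f"unknown column {group_column!r}")
    rng = rng or np.random.default_rng(0)
    out: dict[str, CIResult | None] = {}
    for value, group in table.groupby(group_column, sort=True):
        try:
            out[str(value)] = bootstrap_ci(metric_fn, group.reset_index(drop=True),
                                           n_boot=n_boot, rng=rng)
        except ValueError:
            out[str(value)] = None
    return out
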