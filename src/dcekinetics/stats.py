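"""Group comparison and ROC layer for kinetic markers.

Two-group differences are assessed with the Mann-Whitney U test (exact
permutation distribution at small combined n, tie-corrected normal
approximation with continuity correction otherwise).  Diagnostic
accuracy is summarized by the empirical ROC curve, whose area equals
the Mann-Whitney favorable-pair probability U/(n1*n2); ties receive
half credit consistently in the U statistic, the AUC and the ROC
staircase.  Confidence intervals and paired AUC comparisons use the
DeLong structural-components variance.  Operating thresholds maximize
the Youden index J = sensitivity + specificity - 1.

Direction is always explicit: for markers where smaller values indicate
the positive class (e.g. time-to-maximum-slope in malignant lesions)
the caller says so; an AUC below 0.5 is reported as computed, never
silently flipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "MannWhitneyResult",
    "GroupComparison",
    "RocResult",
    "mann_whitney_u",
    "auc_of_scores",
    "roc_points",
    "youden_threshold",
    "auc_ci_delong",
    "compare_auc_delong",
    "summarize_cohort",
    "DEFAULT_MARKER_DIRECTIONS",
]

Direction = Literal["larger", "smaller"]
SIGNIFICANCE_BANDS = (0.05, 0.01, 0.001)

# Which direction indicates the positive (malignant) class for each
# kinetic marker: rapid, strong early enhancement and late washout.
DEFAULT_MARKER_DIRECTIONS: dict = {
    "a": "larger",
    "b": "smaller",
    "c": "larger",
    "d": "smaller",
    "initial_rate": "larger",
    "delayed_rate": "larger",
}

_EXACT_N_MAX = 12


@dataclass(frozen=True)
class MannWhitneyResult:
    """U statistic (favorable pairs of x over y, half credit for ties)
    and its two-sided p-value."""

    u_statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" or "normal-approx"


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one marker, in summary-table shape."""

    parameter_name: str
    group_stats: dict
    u_statistic: float
    p_value: float
    significant_at: float | None


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve of one marker.

    ``thresholds`` are candidate cutoffs (midpoints between adjacent
    distinct scores plus sentinels beyond the extremes), ascending;
    ``sensitivity``/``specificity`` are aligned per threshold with the
    convention that a test is positive when the score lies on the
    positive-class side of the cutoff (direction-aware).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: Direction
    positive_label: object
    pos_median: float
    auc_ci: tuple | None = None
    ci_degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")


def _pair_score(x: np.ndarray, y: np.ndarray) -> float:
    """Favorable-pair count of x over y with half credit for ties, by
    rank algebra (O(N log N))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided p by full enumeration of the C(n1+n2, n1) group
    labelings of the pooled sample (tie-safe)."""
    pooled = np.concatenate([x, y])
    n = x.size
    total = 0
    extreme = 0
    mu = x.size * y.size / 2.0
    dev_obs = abs(u_obs - mu) - 1e-9
    idx_all = range(pooled.size)
    for comb in combinations(idx_all, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = _pair_score(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= dev_obs:
            extreme += 1
    return extreme / total


def _normal_approx_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n1, n2 = x.size, y.size
    N = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "normal-approx"] = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs (x_i, y_j) with x_i > y_j plus half credit for ties.
    ``mode="auto"`` uses the exact permutation distribution when
    n1 + n2 <= 12 and the tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _pair_score(x, y)
    if mode == "auto":
        mode = "exact" if x.size + y.size <= _EXACT_N_MAX else "normal-approx"
    if mode == "exact":
        p = _exact_two_sided_p(x, y, u)
    elif mode == "normal-approx":
        p = _normal_approx_p(x, y, u)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MannWhitneyResult(u_statistic=u, p_value=p, n_x=x.size, n_y=y.size,
                             method=mode)


def _split_scores(scores, labels, positive_label):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _oriented(pos: np.ndarray, neg: np.ndarray, direction: Direction):
    """Flip signs so that larger oriented score indicates positive."""
    if direction == "larger":
        return pos, neg
    if direction == "smaller":
        return -pos, -neg
    raise ValueError(f"unknown direction {direction!r}")


def auc_of_scores(scores, labels, positive_label, direction: Direction = "larger") -> float:
    """Empirical AUC = favorable-pair fraction with half-credit ties.

    ``direction`` states which side of the score scale indicates the
    positive class; the result is reported as computed (it may fall
    below 0.5 — no orientation is forced).
    """
    pos, neg = _split_scores(scores, labels, positive_label)
    opos, oneg = _oriented(pos, neg, direction)
    return _pair_score(opos, oneg) / (pos.size * neg.size)


def roc_points(scores, labels, positive_label, direction: Direction = "larger") -> RocResult:
    """Empirical ROC staircase of one marker.

    Thresholds are the midpoints between adjacent distinct score values
    plus sentinels beyond both extremes; at each threshold a subject
    tests positive when its score lies on the positive-class side.  The
    trapezoidal area over the resulting points equals the half-credit
    pair-counting AUC.
    """
    pos, neg = _split_scores(scores, labels, positive_label)
    opos, oneg = _oriented(pos, neg, direction)
    pooled = np.concatenate([opos, oneg])
    distinct = np.unique(pooled)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    cuts = np.concatenate([[distinct[0] - 0.5 * span], mids,
                           [distinct[-1] + 0.5 * span]])
    # test positive when oriented score > cut
    sens = np.array([(opos > c).mean() for c in cuts])
    spec = np.array([(oneg <= c).mean() for c in cuts])
    # map oriented cuts back to the original score scale
    thresholds = cuts if direction == "larger" else -cuts
    order = np.argsort(thresholds)
    auc = _pair_score(opos, oneg) / (pos.size * neg.size)
    return RocResult(
        thresholds=thresholds[order],
        sensitivity=sens[order],
        specificity=spec[order],
        auc=auc,
        direction=direction,
        positive_label=positive_label,
        pos_median=float(np.median(pos)),
    )


def youden_threshold(roc: RocResult) -> float:
    """Cutoff maximizing the Youden index J = sens + spec - 1.

    Ties are broken toward the threshold nearest the positive-class
    median score.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    jmax = j.max()
    candidates = np.flatnonzero(j >= jmax - 1e-12)
    if len(candidates) > 1:
        dist = np.abs(roc.thresholds[candidates] - roc.pos_median)
        candidates = candidates[np.argsort(dist, kind="stable")]
    return float(roc.thresholds[candidates[0]])


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Structural components: V10 per positive, V01 per negative."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def auc_ci_delong(scores, labels, positive_label, direction: Direction = "larger",
                  level: float = 0.95):
    """DeLong 95% confidence interval for the empirical AUC.

    Returns ``(auc, (lo, hi), degenerate)``; when the variance is zero
    (perfect or inverted separation) the interval collapses to the
    point and is flagged degenerate.
    """
    pos, neg = _split_scores(scores, labels, positive_label)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 subjects per class")
    opos, oneg = _oriented(pos, neg, direction)
    v10, v01, auc = _delong_components(opos, oneg)
    var = np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size
    if var <= 0:
        return float(auc), (float(auc), float(auc)), True
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    lo = max(0.0, auc - half)
    hi = min(1.0, auc + half)
    return float(auc), (float(lo), float(hi)), False


def compare_auc_delong(
    scores_a, scores_b, labels, positive_label,
    direction_a: Direction = "larger", direction_b: Direction = "larger",
) -> float:
    """Paired DeLong test for the difference of two AUCs measured on the
    same subjects.  Returns the two-sided p-value."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.size != scores_b.size or scores_a.size != labels.size:
        raise ValueError("paired markers must share the same subjects")
    pos_a, neg_a = _split_scores(scores_a, labels, positive_label)
    pos_b, neg_b = _split_scores(scores_b, labels, positive_label)
    oa = _oriented(pos_a, neg_a, direction_a)
    ob = _oriented(pos_b, neg_b, direction_b)
    v10_a, v01_a, auc_a = _delong_components(*oa)
    v10_b, v01_b, auc_b = _delong_components(*ob)
    m, n = pos_a.size, neg_a.size
    var = (np.var(v10_a - v10_b, ddof=1) / m
           + np.var(v01_a - v01_b, ddof=1) / n)
    d = auc_a - auc_b
    if var <= 0:
        return 1.0 if d == 0 else 0.0
    z = d / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _significance_band(p: float) -> float | None:
    band = None
    for alpha in SIGNIFICANCE_BANDS:
        if p < alpha:
            band = alpha
    return band


def _marker_values(record, marker: str) -> float:
    from .model import delayed_enhancement_rate, initial_enhancement_rate

    if marker in ("a", "b", "c", "d"):
        if record.fit is None:
            raise ValueError(f"record {record.lesion_id} has no fit")
        return getattr(record.fit.params, marker)
    if marker == "initial_rate":
        return initial_enhancement_rate(record.curve)
    if marker == "delayed_rate":
        return delayed_enhancement_rate(record.curve)
    raise ValueError(f"unknown marker {marker!r}")


def compare_groups(
    values_pos, values_neg, name: str, labels_pair: tuple
) -> GroupComparison:
    """Mann-Whitney comparison plus per-group summary statistics."""
    res = mann_whitney_u(values_pos, values_neg)
    stats = {}
    for label, vals in zip(labels_pair, (values_pos, values_neg)):
        v = np.asarray(vals, dtype=float)
        stats[label] = {
            "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
            "median": float(np.median(v)), "n": int(v.size),
        }
    return GroupComparison(
        parameter_name=name, group_stats=stats,
        u_statistic=res.u_statistic, p_value=res.p_value,
        significant_at=_significance_band(res.p_value),
    )


def summarize_cohort(
    records: Sequence,
    grouping: tuple,
    markers: Sequence[str] = ("a", "b", "c", "d", "initial_rate", "delayed_rate"),
    directions: Mapping[str, Direction] | None = None,
) -> pd.DataFrame:
    """Per-marker group-comparison and ROC summary table.

    ``grouping`` is (positive_label, negative_label); each marker row
    reports group mean +/- SD, the Mann-Whitney p-value, AUC with
    DeLong 95% CI, the Youden threshold and the sensitivity/specificity
    attained there.  The late slope ``d`` is reported on the 1e-4 scale
    used in the field's tables.
    """
    directions = dict(DEFAULT_MARKER_DIRECTIONS, **(directions or {}))
    pos_label, neg_label = grouping
    recs = [r for r in records if r.group in grouping]
    if not recs:
        raise ValueError(f"no records in groups {grouping}")
    for label in grouping:
        n = sum(r.group == label for r in recs)
        if n < 2:
            raise ValueError(f"group {label!r} has {n} member(s); need >= 2")

    rows = []
    for marker in markers:
        vals = np.array([_marker_values(r, marker) for r in recs])
        labels = np.array([r.group for r in recs])
        scale = 1e4 if marker == "d" else 1.0
        comp = compare_groups(vals[labels == pos_label] * scale,
                              vals[labels == neg_label] * scale,
                              marker, grouping)
        direction = directions.get(marker, "larger")
        auc, ci, degen = auc_ci_delong(vals * scale, labels, pos_label, direction)
        roc = roc_points(vals * scale, labels, pos_label, direction)
        thr = youden_threshold(roc)
        idx = int(np.argmin(np.abs(roc.thresholds - thr)))
        rows.append({
            "marker": marker,
            f"mean_{pos_label}": comp.group_stats[pos_label]["mean"],
            f"sd_{pos_label}": comp.group_stats[pos_label]["sd"],
            f"mean_{neg_label}": comp.group_stats[neg_label]["mean"],
            f"sd_{neg_label}": comp.group_stats[neg_label]["sd"],
            "u_statistic": comp.u_statistic,
            "p_value": comp.p_value,
            "significant_at": comp.significant_at,
            "auc": auc,
            "auc_ci_low": ci[0],
            "auc_ci_high": ci[1],
            "threshold": thr,
            "sensitivity": roc.sensitivity[idx],
            "specificity": roc.specificity[idx],
            "direction": direction,
        })
    return pd.DataFrame(rows)
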