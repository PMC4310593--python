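"""Cohort-level inference on per-site measurements.

Group comparison follows the original analysis plan: single-factor
ANOVA with Tukey's honest-significant-difference post hoc test, box-plot
summaries (median, quartiles, 1.5×IQR outliers), and an empirical ROC
for normal vs pooled dysplasia with the area under the curve and a
Youden-optimal operating point reported as sensitivity/specificity plus
within-class TP/FP/TN/FN rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn import metrics as skmetrics

__all__ = [
    "GroupSummary",
    "ROCResult",
    "OperatingPoint",
    "one_way_anova",
    "tukey_hsd",
    "group_summary",
    "summarize_groups",
    "empirical_roc",
    "operating_point",
]


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    if sum(len(g) for g in gs) <= len(gs):
        raise ValueError("total n must exceed the number of groups")
    return gs


def one_way_anova(groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA: (F statistic, p-value).

    Degenerate case: if every group has zero within-group variance the F
    ratio is undefined; we report F = inf, p = 0 when the means differ
    and F = 0, p = 1 when they do not.
    """
    gs = _check_groups(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0:
        means = [g.mean() for g in gs]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = sstats.f_oneway(*gs)
    return float(f), float(p)


def tukey_hsd(groups) -> np.ndarray:
    """Tukey HSD adjusted p-values for every pair of groups.

    Uses the studentized-range distribution with the pooled within-group
    variance; returns a symmetric (k, k) matrix of adjusted p-values.
    """
    gs = _check_groups(groups)
    if sum(((g - g.mean()) ** 2).sum() for g in gs) == 0:
        k = len(gs)
        means = np.array([g.mean() for g in gs])
        p = np.ones((k, k))
        diff = means[:, None] != means[None, :]
        p[diff] = 0.0
        np.fill_diagonal(p, 1.0)
        return p
    res = sstats.tukey_hsd(*gs)
    return np.asarray(res.pvalue, dtype=float)


@dataclass
class GroupSummary:
    """Box-plot statistics of one group."""

    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    outliers: np.ndarray


def group_summary(values) -> GroupSummary:
    """Median, quartiles (linear-interpolation convention) and 1.5×IQR
    outliers for one group of values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("group must be non-empty")
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    return GroupSummary(
        n=int(v.size), mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=float(med), q25=float(q25), q75=float(q75),
        outliers=np.sort(v[(v < lo) | (v > hi)]),
    )


def summarize_groups(frame, value_col: str = "delta_linearity",
                     group_col: str = "group"):
    """Per-group box-plot summary table from a cohort DataFrame."""
    import pandas as pd

    rows = []
    for name, sub in frame.groupby(group_col, sort=True):
        s = group_summary(sub[value_col].to_numpy())
        rows.append({group_col: name, "n": s.n, "mean": s.mean, "sd": s.sd,
                     "median": s.median, "q25": s.q25, "q75": s.q75,
                     "n_outliers": len(s.outliers)})
    return pd.DataFrame(rows)


@dataclass
class ROCResult:
    """Empirical ROC: thresholds, per-threshold sensitivity/specificity,
    trapezoid AUC, and (once chosen) the optimum operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating: "OperatingPoint | None" = None


@dataclass
class OperatingPoint:
    """Optimum ROC cutoff with its classification rates.

    ``rates`` are proportions within each true class, so TP + FN = 1 and
    TN + FP = 1.
    """

    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    youden_j: float
    rates: dict = field(default_factory=dict)


def empirical_roc(scores, labels) -> ROCResult:
    """Empirical ROC over all distinct score thresholds.

    ``labels`` are truthy for the positive (dysplastic) class and a
    higher score indicates dysplasia; a score >= cutoff classifies
    positive. The AUC is the trapezoid area, equal to the normalized
    rank-sum (concordance) statistic with ties counted 1/2.
    """
    y = np.asarray(labels, dtype=bool).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = skmetrics.roc_curve(y, s)
    auc = float(skmetrics.auc(fpr, tpr))
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def operating_point(roc: ROCResult, criterion: str = "youden") -> OperatingPoint:
    """Choose the optimum ROC cutoff.

    ``"youden"`` maximizes J = sensitivity + specificity − 1;
    ``"closest"`` minimizes the distance to the (0, 1) corner. Ties go
    to the lower cutoff. The chosen point is also stored on ``roc``.
    """
    sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
    if criterion == "youden":
        obj = sens + spec - 1.0
    elif criterion == "closest":
        obj = -np.hypot(1.0 - sens, 1.0 - spec)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    # thresholds are sorted descending; argmax of reversed view -> lowest cutoff
    best = len(obj) - 1 - int(np.argmax(obj[::-1]))
    op = OperatingPoint(
        cutoff=float(thr[best]),
        sensitivity_pct=float(100 * sens[best]),
        specificity_pct=float(100 * spec[best]),
        youden_j=float(sens[best] + spec[best] - 1.0),
        rates={"TP": float(sens[best]), "FN": float(1 - sens[best]),
               "TN": float(spec[best]), "FP": float(1 - spec[best])},
    )
    roc.operating = op
    return op
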