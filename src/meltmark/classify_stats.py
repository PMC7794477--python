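"""ROC classification and rank statistics for case/control biomarker scores.

The classification convention throughout is "higher score implies case", and a
sample is predicted positive when its score is greater than or equal to the
cutoff, so every reported cutoff is itself an attainable operating point. The
optimal cutoff is Youden-style: it maximizes TPR - FPR, with ties broken in
favor of the more specific operating point (lower FPR, then higher cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.stats

from ._utils import as_float_array

Alternative = Literal["two-sided", "less", "greater"]


@dataclass(frozen=True)
class OptimalPoint:
    """A Youden-optimal ROC operating point."""

    cutoff: float
    tpr: float
    fpr: float

    @property
    def sensitivity(self) -> float:
        return self.tpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr


@dataclass(frozen=True)
class RocResult:
    """A full ROC curve with its AUC and Youden-optimal operating point.

    ``thresholds`` are sorted in decreasing order, starting with ``+inf`` (the
    classify-nothing operating point); ``tpr[i]`` and ``fpr[i]`` are the rates
    obtained by predicting positive whenever score >= ``thresholds[i]``.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal: OptimalPoint
    n_cases: int
    n_controls: int

    @property
    def optimal_cutoff(self) -> float:
        return self.optimal.cutoff

    @property
    def sensitivity(self) -> float:
        return self.optimal.tpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.optimal.fpr

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(t) for t in self.thresholds],
            "tpr": [float(t) for t in self.tpr],
            "fpr": [float(f) for f in self.fpr],
            "auc": float(self.auc),
            "optimal_cutoff": float(self.optimal.cutoff),
            "sensitivity": float(self.optimal.tpr),
            "specificity": float(1.0 - self.optimal.fpr),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample (mid-ranks for ties)
    p_value: float
    method: str = field(default="exact", compare=False)


def roc_curve(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    direction: Literal["greater", "less"] = "greater",
) -> RocResult:
    """Build the empirical ROC curve for cases versus controls.

    ``direction="greater"`` (default) means a higher score indicates a case;
    ``"less"`` flips the sign of all scores first. Candidate thresholds are
    the distinct observed scores plus a ``+inf`` sentinel. The AUC is computed
    by the trapezoidal rule and equals the Mann-Whitney U statistic scaled by
    ``n_cases * n_controls``, with tied case/control scores counted 1/2.
    """
    cases = as_float_array(case_scores, "case_scores")
    controls = as_float_array(control_scores, "control_scores")
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control score")
    if direction == "less":
        cases, controls = -cases, -controls
    elif direction != "greater":
        raise ValueError(f"unknown direction {direction!r}")

    thresholds = np.concatenate(
        [[np.inf], np.unique(np.concatenate([cases, controls]))[::-1]]
    )
    # score >= threshold  =>  predicted positive
    tpr = np.array([(cases >= t).mean() for t in thresholds])
    fpr = np.array([(controls >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    opt = _optimal_point(thresholds, tpr, fpr)
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        optimal=opt,
        n_cases=cases.size,
        n_controls=controls.size,
    )


def _optimal_point(thresholds: np.ndarray, tpr: np.ndarray, fpr: np.ndarray) -> OptimalPoint:
    youden = tpr - fpr
    best = 0
    for i in range(1, len(thresholds)):
        if youden[i] > youden[best] + 1e-12:
            best = i
        elif abs(youden[i] - youden[best]) <= 1e-12:
            # ties: prefer lower FPR, then higher threshold
            if fpr[i] < fpr[best] - 1e-12:
                best = i
            elif abs(fpr[i] - fpr[best]) <= 1e-12 and thresholds[i] > thresholds[best]:
                best = i
    return OptimalPoint(
        cutoff=float(thresholds[best]), tpr=float(tpr[best]), fpr=float(fpr[best])
    )


def optimal_cutoff(roc: RocResult) -> OptimalPoint:
    """The operating point maximizing TPR - FPR (ties: lower FPR, higher cutoff)."""
    return _optimal_point(roc.thresholds, roc.tpr, roc.fpr)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two-sided",
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    The p-value comes from exact enumeration when the combined sample size is
    at most 12 and there are no ties, and otherwise from the normal
    approximation with tie-corrected variance and continuity correction.
    ``alternative="less"`` tests the one-sided hypothesis that ``x`` tends to
    be smaller than ``y``. The reported statistic is the rank sum of ``x``
    (mid-ranks for ties).
    """
    xa = as_float_array(x, "x")
    ya = as_float_array(y, "y")
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([xa, ya])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        xa, ya, alternative=alternative, method=method, use_continuity=True
    )
    rank_sum = float(res.statistic) + xa.size * (xa.size + 1) / 2.0
    return RankSumResult(statistic=rank_sum, p_value=float(res.pvalue), method=method)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; ``None`` when undefined (constant input or n < 2)."""
    xa = as_float_array(x, "x")
    ya = as_float_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 2 or np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return None
    return float(scipy.stats.pearsonr(xa, ya).statistic)
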