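"""Fall-risk diagnostic evaluation: labeling, ROC/AUC, cut-offs, metrics.

Subjects are labeled fallers either from clinical criteria — Berg Balance
Scale below 40 or Timed Up and Go over 14 s — or from 3-month fall
history.  Sway scores are then evaluated as a diagnostic test: the ROC
curve sweeps a threshold over the scores with the rule *score ≥ threshold
⇒ predicted faller* (higher sway indicates higher fall risk), the area
under it (AUC) equals the probability that a random faller outscores a
random non-faller (ties counted one half), and the operating cut-off is
chosen by Youden's index J = max(sensitivity + specificity − 1).

The AUC standard error uses the Hanley–McNeil nonparametric formula with
a normal 95% interval clipped to [0, 1].  Group comparisons of summary
statistics use Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DataError, DegenerateCohortError, ValidationError
from .features import SwayFeatureSet

BBS_MAX = 56
DEFAULT_BBS_THRESHOLD = 40
DEFAULT_TUG_THRESHOLD_S = 14.0

GRADE_BANDS = (
    (0.81, "excellent"),
    (0.61, "good"),
    (0.41, "moderate"),
    (0.0, "poor"),
)

DIRECTIONS = ("AP", "ML", "V", "mean")


@dataclass
class SubjectRecord:
    """One participant: clinical scores, fall history and sway scores."""

    subject_id: str
    group: Literal["healthy", "MCI"]
    bbs_score: int | None = None
    tug_seconds: float | None = None
    fell_within_3_months: bool | None = None
    sway_scores: dict[str, float] = field(default_factory=dict)
    sway: SwayFeatureSet | None = None

    def __post_init__(self) -> None:
        if self.bbs_score is not None and not 0 <= self.bbs_score <= BBS_MAX:
            raise ValidationError(
                f"{self.subject_id}: BBS score {self.bbs_score} outside [0, {BBS_MAX}]"
            )
        if self.tug_seconds is not None and self.tug_seconds <= 0:
            raise ValidationError(
                f"{self.subject_id}: TUG time must be positive"
            )
        if self.sway is not None and not self.sway_scores:
            self.sway_scores = dict(self.sway.axis_scores)
            self.sway_scores["mean"] = self.sway.mean_score

    def score(self, direction: str) -> float:
        if direction not in self.sway_scores:
            raise DataError(
                f"{self.subject_id}: no sway score for direction {direction!r}"
            )
        return float(self.sway_scores[direction])


@dataclass(frozen=True)
class FallCriterion:
    """How subjects are labeled positive (at risk of falls / faller).

    ``bbs`` mode: positive iff BBS < ``bbs_threshold`` (strict by default;
    an inclusive ``<=`` variant is available since the clinical literature
    phrases the 100%-risk band as "40 or less").  ``tug`` mode: positive
    iff TUG > ``tug_threshold``.  ``history`` mode: positive iff the
    subject fell within the last 3 months.
    """

    mode: Literal["bbs", "tug", "history"] = "bbs"
    bbs_threshold: int = DEFAULT_BBS_THRESHOLD
    tug_threshold: float = DEFAULT_TUG_THRESHOLD_S
    bbs_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("bbs", "tug", "history"):
            raise ValidationError(f"unknown criterion mode {self.mode!r}")
        if not 0 < self.bbs_threshold <= BBS_MAX:
            raise ValidationError("BBS threshold outside the 0–56 score range")
        if self.tug_threshold <= 0:
            raise ValidationError("TUG threshold must be positive")


def label_faller(record: SubjectRecord, criterion: FallCriterion) -> bool:
    """Apply the fall criterion to one subject."""
    if criterion.mode == "bbs":
        if record.bbs_score is None:
            raise DataError(f"{record.subject_id}: BBS score required for bbs mode")
        if criterion.bbs_inclusive:
            return record.bbs_score <= criterion.bbs_threshold
        return record.bbs_score < criterion.bbs_threshold
    if criterion.mode == "tug":
        if record.tug_seconds is None:
            raise DataError(f"{record.subject_id}: TUG time required for tug mode")
        return record.tug_seconds > criterion.tug_threshold
    if record.fell_within_3_months is None:
        raise DataError(
            f"{record.subject_id}: fall history required for history mode"
        )
    return bool(record.fell_within_3_months)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocSummary:
    """ROC curve plus derived summaries for one score/label pairing.

    ``thresholds`` are in descending order starting from an ``inf``
    sentinel (nothing predicted positive); ``sensitivity`` and ``fpr``
    (1 − specificity) are both nondecreasing along the sweep.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int
    auc: float = float("nan")
    se: float = float("nan")
    ci95: tuple[float, float] = (float("nan"), float("nan"))
    cutoff: float = float("nan")
    youden_j: float = float("nan")

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


def _as_label_array(labels: Sequence[bool]) -> np.ndarray:
    y = np.asarray(labels, dtype=bool)
    return y


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocSummary:
    """Sweep thresholds over the scores and trace the ROC curve.

    Prediction rule: score ≥ threshold ⇒ positive.  Thresholds are the
    unique score values in descending order, preceded by an ``inf``
    sentinel so the curve starts at (0, 0); it ends at (1, 1) at the
    lowest score.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_label_array(labels)
    if s.size != y.size:
        raise ValidationError("scores and labels differ in length")
    if s.size == 0:
        raise ValidationError("empty cohort")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateCohortError(
            f"both classes required for ROC analysis (got {n_pos} positive, "
            f"{n_neg} negative)"
        )
    # sort-based sweep: at threshold = each distinct score (descending),
    # cumulative positive/negative counts give sensitivity and FPR
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    last_of_tie = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[last_of_tie]
    fp = np.cumsum(~y_sorted)[last_of_tie]
    thresholds = np.concatenate([[np.inf], s_sorted[last_of_tie]])
    sens = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return RocSummary(
        thresholds=thresholds, sensitivity=sens, fpr=fpr, n_pos=n_pos, n_neg=n_neg
    )


def auc(roc: RocSummary) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann–Whitney pair-counting probability that a random
    positive outscores a random negative, with tied pairs counted ½.
    """
    return float(np.trapezoid(roc.sensitivity, roc.fpr))


def auc_se_ci(
    roc: RocSummary, n_pos: int | None = None, n_neg: int | None = None
) -> tuple[float, tuple[float, float]]:
    """Hanley–McNeil standard error and normal 95% CI for the AUC.

    SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊ n₋) with
    Q₁ = A/(2−A) and Q₂ = 2A²/(1+A); the interval A ± 1.96·SE is clipped
    to [0, 1].
    """
    n_pos = roc.n_pos if n_pos is None else n_pos
    n_neg = roc.n_neg if n_neg is None else n_neg
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("need at least one subject in each class")
    a = auc(roc) if np.isnan(roc.auc) else roc.auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    lo = float(np.clip(a - 1.96 * se, 0.0, 1.0))
    hi = float(np.clip(a + 1.96 * se, 0.0, 1.0))
    return se, (lo, hi)


def youden_cutoff(roc: RocSummary) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Ties are broken by higher sensitivity, then by lower threshold.  The
    ``inf`` sentinel is never returned: if the maximum J occurs there
    (J = 0 for an uninformative curve), the lowest-threshold attainment of
    the same J is preferred by the tie-break.
    """
    j = roc.sensitivity - roc.fpr
    # lexicographic argmax: J, then sensitivity, then -threshold
    order = sorted(
        range(len(j)),
        key=lambda i: (j[i], roc.sensitivity[i], -roc.thresholds[i]),
        reverse=True,
    )
    best = order[0]
    thr = roc.thresholds[best]
    if np.isinf(thr):  # only possible when every J ties at the sentinel
        thr = roc.thresholds[-1]
    return float(thr), float(j[best])


def summarize_roc(scores: Sequence[float], labels: Sequence[bool]) -> RocSummary:
    """Full ROC summary: curve, AUC, SE/CI, Youden cut-off."""
    roc = roc_curve(scores, labels)
    roc.auc = auc(roc)
    roc.se, roc.ci95 = auc_se_ci(roc)
    roc.cutoff, roc.youden_j = youden_cutoff(roc)
    return roc


# ---------------------------------------------------------------------------
# Confusion-matrix metrics and grading
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, accuracy and their qualitative grades.

    A zero denominator (no positives for sensitivity, no negatives for
    specificity) yields NaN rather than an exception, with grade ``None``.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    grades: dict[str, str | None] = field(default_factory=dict)


def confusion(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> ConfusionCounts:
    """Confusion counts under the rule score ≥ cutoff ⇒ predicted positive."""
    s = np.asarray(scores, dtype=float)
    y = _as_label_array(labels)
    if s.size != y.size:
        raise ValidationError("scores and labels differ in length")
    pred = s >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def metrics(c: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N."""
    if c.total == 0:
        raise ValidationError("empty cohort")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    acc = (c.tp + c.tn) / c.total
    grades = {
        "sensitivity": grade(sens) if not np.isnan(sens) else None,
        "specificity": grade(spec) if not np.isnan(spec) else None,
        "accuracy": grade(acc),
    }
    return DiagnosticMetrics(
        sensitivity=sens, specificity=spec, accuracy=acc, grades=grades
    )


def grade(value: float) -> str:
    """Qualitative band for a proportion: excellent ≥ 0.81, good ≥ 0.61,
    moderate ≥ 0.41, else poor."""
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"proportion {value} outside [0, 1]")
    for lower, name in GRADE_BANDS:
        if value >= lower:
            return name
    return "poor"  # pragma: no cover — bands reach 0.0


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def group_compare(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> tuple[float, float]:
    """Welch's two-sided t-test from group summary statistics.

    Returns (t statistic, p-value).  Welch's unequal-variance form is used
    because the groups compared here (young healthy adults vs older adults
    with MCI) have visibly different spreads.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs n ≥ 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValidationError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=False
    )
    return float(res.statistic), float(res.pvalue)
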