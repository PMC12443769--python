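"""LOCS III cataract grades and the grading-evaluation battery.

The Lens Opacities Classification System III grades nuclear cataract on a
1.0-6.0 continuous scale (nuclear colour) and cortical / posterior
subcapsular cataract on 1.0-5.0 (transparency), at 0.1 resolution.  An
automated grader is evaluated against a gold-standard grader through:

* the absolute grading error per eye and Re1.0, the percentage of eyes
  graded within 1.0 unit of the gold standard;
* ICC(2,1) — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation;
* binary diagnostic metrics (accuracy / sensitivity / specificity) for the
  surgical-indication flag, where surgery is indicated when the nuclear or
  the cortical grade exceeds 3.5;
* ROC analysis of the continuous predicted grade against the gold-standard
  surgical flag, with DeLong's method for the AUC variance, confidence
  interval, and correlated-AUC comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "CataractSubtype",
    "LocsGrade",
    "GRADE_RANGES",
    "grading_error",
    "re_1_0",
    "surgical_indication",
    "BinaryMetrics",
    "binary_metrics",
    "IccResult",
    "icc_absolute",
    "RocResult",
    "roc_auc",
    "DelongResult",
    "delong_compare",
    "auc_confidence_interval",
]


class CataractSubtype(str, Enum):
    NUCLEAR = "nuclear"
    CORTICAL = "cortical"
    PSC = "psc"  # posterior subcapsular


#: Valid LOCS III grade range per cataract subtype.
GRADE_RANGES: dict[CataractSubtype, tuple[float, float]] = {
    CataractSubtype.NUCLEAR: (1.0, 6.0),
    CataractSubtype.CORTICAL: (1.0, 5.0),
    CataractSubtype.PSC: (1.0, 5.0),
}


@dataclass(frozen=True)
class LocsGrade:
    """A LOCS III grade for one cataract subtype of one eye."""

    subtype: CataractSubtype
    value: float

    def __post_init__(self) -> None:
        subtype = self.subtype
        if isinstance(subtype, str) and not isinstance(subtype, CataractSubtype):
            subtype = CataractSubtype(subtype)
            object.__setattr__(self, "subtype", subtype)
        lo, hi = GRADE_RANGES[subtype]
        if not (lo <= self.value <= hi):
            raise ValueError(
                f"{subtype.value} grade {self.value} outside LOCS III range [{lo}, {hi}]"
            )


def _grade_value(g: "LocsGrade | float") -> float:
    return g.value if isinstance(g, LocsGrade) else float(g)


def grading_error(predicted: LocsGrade, gold: LocsGrade) -> float:
    """Absolute difference between a predicted and a gold-standard grade."""
    if predicted.subtype != gold.subtype:
        raise ValueError(
            f"subtype mismatch: {predicted.subtype.value} vs {gold.subtype.value}"
        )
    return abs(predicted.value - gold.value)


def re_1_0(errors: Sequence[float], threshold: float = 1.0) -> float:
    """Percentage of grading errors ≤ ``threshold`` (Re1.0 for the default).

    The boundary counts as within: an error of exactly 1.0 passes.
    """
    err = np.asarray(errors, dtype=float)
    if err.size == 0:
        raise ValueError("Re1.0 undefined for an empty error list")
    if (err < 0).any():
        raise ValueError("grading errors must be non-negative")
    return 100.0 * float(np.mean(err <= threshold))


def surgical_indication(
    nuclear: LocsGrade | float,
    cortical: LocsGrade | float,
    threshold: float = 3.5,
) -> bool:
    """Cataract-surgery indication from the grading alone.

    Surgery is indicated when the nuclear grade or the cortical grade is
    strictly greater than ``threshold`` (default 3.5; a grade of exactly
    3.5 does not indicate).
    """
    return _grade_value(nuclear) > threshold or _grade_value(cortical) > threshold


@dataclass(frozen=True)
class BinaryMetrics:
    """2x2 diagnostic metrics; an undefined ratio (empty margin) is None."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    tp: int
    tn: int
    fp: int
    fn: int


def binary_metrics(
    predicted_flags: Sequence[bool], gold_flags: Sequence[bool]
) -> BinaryMetrics:
    """Accuracy, sensitivity and specificity of predicted vs gold flags.

    Positives are defined by the gold flags:
    accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).
    """
    pred = np.asarray(predicted_flags, dtype=bool)
    gold = np.asarray(gold_flags, dtype=bool)
    if pred.shape != gold.shape or pred.ndim != 1:
        raise ValueError("predicted and gold flag lists must be equal-length 1-D")
    if pred.size == 0:
        raise ValueError("cannot compute metrics on empty input")
    tp = int(np.sum(pred & gold))
    tn = int(np.sum(~pred & ~gold))
    fp = int(np.sum(pred & ~gold))
    fn = int(np.sum(~pred & gold))
    accuracy = (tp + tn) / pred.size
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    return BinaryMetrics(accuracy, sensitivity, specificity, tp, tn, fp, fn)


@dataclass(frozen=True)
class IccResult:
    """ICC(2,1) with the mean squares it was derived from.

    ``msr``/``msc``/``mse`` are the between-subject, between-rater and
    residual mean squares of the two-way ANOVA, so other ICC forms can be
    recomputed from the same decomposition.
    """

    value: float | None
    msr: float
    msc: float
    mse: float
    n: int
    k: int = 2


def icc_absolute(pairs: Sequence[tuple[float, float]]) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    This form treats both raters as random draws and penalises systematic
    offsets between them, which is the clinically relevant question when
    comparing an automated grader against a gold standard.  Requires at
    least 3 pairs; returns ``value=None`` when total variance is zero.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (rater_a, rater_b) tuples")
    n, k = data.shape
    if n < 3:
        raise ValueError(f"ICC needs at least 3 pairs, got {n}")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_total == 0.0 or denom == 0.0:
        return IccResult(value=None, msr=msr, msc=msc, mse=mse, n=n, k=k)
    return IccResult(value=(msr - mse) / denom, msr=msr, msc=msc, mse=mse, n=n, k=k)


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or (~labels).all():
        raise ValueError("ROC analysis needs both positive and negative labels")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve and AUC of continuous scores against binary labels.

    The AUC is computed through the Mann-Whitney identity — the probability
    that a random positive outscores a random negative, ties counting 1/2 —
    which equals the trapezoidal area under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    _check_two_classes(y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    # Mann-Whitney via midranks: AUC = (rank-sum of positives - offset) / (n+ n-)
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr)


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: per-positive and per-negative components."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)  # one per positive
    v01 = psi.mean(axis=0)  # one per negative
    auc = psi.mean()
    return auc, v10, v01, m, n


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float | None
    p_value: float | None


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> DelongResult:
    """DeLong's test for two correlated AUCs measured on the same eyes.

    Both score vectors are paired with the same label vector.  Variances and
    the covariance come from the structural-components (placement-value)
    estimator; the p-value is the two-sided normal approximation for the
    AUC difference.  A degenerate variance of the difference yields
    ``z=None, p_value=None``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape) or a.ndim != 1:
        raise ValueError("scores_a, scores_b and labels must be equal-length 1-D")
    _check_two_classes(y)

    auc_a, v10_a, v01_a, m, n = _structural_components(a, y)
    auc_b, v10_b, v01_b, _, _ = _structural_components(b, y)

    def _cov(x, yv):
        if x.size < 2:
            return 0.0
        return float(np.cov(x, yv, ddof=1)[0, 1])

    var_a = _cov(v10_a, v10_a) / m + _cov(v01_a, v01_a) / n
    var_b = _cov(v10_b, v10_b) / m + _cov(v01_b, v01_b) / n
    cov_ab = _cov(v10_a, v10_b) / m + _cov(v01_a, v01_b) / n

    var_diff = var_a + var_b - 2 * cov_ab
    if var_diff <= 0:
        # identical or perfectly separated scores: no sampling variance left
        z = None
        p = 1.0 if math.isclose(auc_a, auc_b) else None
    else:
        z = (auc_a - auc_b) / math.sqrt(var_diff)
        p = 2 * stats.norm.sf(abs(z))
    return DelongResult(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        var_a=var_a,
        var_b=var_b,
        cov_ab=cov_ab,
        z=z,
        p_value=p,
    )


def auc_confidence_interval(
    scores: Sequence[float], labels: Sequence[bool], level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Single-AUC normal-approximation CI from the DeLong variance.

    Returns ``(auc, (lo, hi))`` with the interval clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    auc, v10, v01, m, n = _structural_components(s, y)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = stats.norm.ppf(0.5 + level / 2) * math.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))
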