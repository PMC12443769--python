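"""Visual-acuity representation, conversion, grouping and prediction evaluation.

Best-corrected visual acuity (BCVA) arrives in three notations: a Snellen
fraction (e.g. 6/12), a logMAR value, or one of the off-chart categorical
codes used for very poor vision (counting fingers, hand motion, light
perception, no light perception).  Everything downstream works in logMAR
(logarithm of the minimum angle of resolution; lower is better), so this
module owns the conversions and the prediction-error statistics computed on
the logMAR scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "VAKind",
    "VACategory",
    "VAMeasure",
    "VAPredictionEval",
    "CATEGORY_LOGMAR",
    "to_logmar",
    "parse_va",
    "classify_va_group",
    "evaluate_predictions",
]


class VAKind(str, Enum):
    SNELLEN = "snellen"
    LOGMAR = "logmar"
    CATEGORICAL = "categorical"


class VACategory(str, Enum):
    """Off-chart acuity codes, worst to merely very poor: NLP > LP > HM > CF."""

    CF = "CF"   # counting fingers
    HM = "HM"   # hand motion
    LP = "LP"   # light perception
    NLP = "NLP"  # no light perception


#: Conventional logMAR equivalents assigned to the categorical codes.
CATEGORY_LOGMAR: dict[VACategory, float] = {
    VACategory.CF: 1.9,
    VACategory.HM: 2.3,
    VACategory.LP: 2.7,
    VACategory.NLP: 3.0,
}


@dataclass(frozen=True)
class VAMeasure:
    """One acuity measurement in exactly one of the three notations.

    Use the constructors :meth:`snellen`, :meth:`logmar` and
    :meth:`categorical` rather than filling fields by hand.
    """

    kind: VAKind
    snellen_num: float | None = None
    snellen_den: float | None = None
    logmar_value: float | None = None
    category: VACategory | None = None

    def __post_init__(self) -> None:
        if self.kind == VAKind.SNELLEN:
            if self.snellen_num is None or self.snellen_den is None:
                raise ValueError("Snellen measure requires numerator and denominator")
            if self.snellen_num <= 0 or self.snellen_den <= 0:
                raise ValueError(
                    f"Snellen components must be positive, got "
                    f"{self.snellen_num}/{self.snellen_den}"
                )
        elif self.kind == VAKind.LOGMAR:
            if self.logmar_value is None or not math.isfinite(self.logmar_value):
                raise ValueError(f"logMAR value must be finite, got {self.logmar_value}")
        elif self.kind == VAKind.CATEGORICAL:
            if not isinstance(self.category, VACategory):
                raise ValueError(f"unknown categorical acuity code: {self.category!r}")

    @classmethod
    def snellen(cls, num: float, den: float) -> "VAMeasure":
        return cls(kind=VAKind.SNELLEN, snellen_num=num, snellen_den=den)

    @classmethod
    def logmar(cls, value: float) -> "VAMeasure":
        return cls(kind=VAKind.LOGMAR, logmar_value=value)

    @classmethod
    def categorical(cls, code: str | VACategory) -> "VAMeasure":
        if isinstance(code, str):
            try:
                code = VACategory[code.strip().upper()]
            except KeyError:
                raise ValueError(f"unknown categorical acuity code: {code!r}") from None
        return cls(kind=VAKind.CATEGORICAL, category=code)


def to_logmar(va: VAMeasure, rounding: int | None = 2) -> float:
    """Convert a :class:`VAMeasure` to logMAR.

    Snellen fractions convert as ``log10(den/num)``, rounded to ``rounding``
    decimal places by default (so 6/12 reports as the conventional 0.30
    rather than 0.30103; pass ``rounding=None`` for the raw value).
    Categorical codes use the fixed table CF=1.9, HM=2.3, LP=2.7, NLP=3.0.
    logMAR input is returned unchanged (never rounded).
    """
    if not isinstance(va, VAMeasure):
        raise TypeError(f"expected VAMeasure, got {type(va).__name__}")
    if va.kind == VAKind.LOGMAR:
        return float(va.logmar_value)
    if va.kind == VAKind.CATEGORICAL:
        return CATEGORY_LOGMAR[va.category]
    value = math.log10(va.snellen_den / va.snellen_num)
    if rounding is not None:
        value = round(value, rounding)
    return value


def parse_va(text: str | float, rounding: int | None = 2) -> float:
    """Parse a free-form VA cell ("6/12", "0.30", "hm") to logMAR.

    Accepts Snellen fractions with ``/``, plain numbers interpreted as
    logMAR, and the categorical codes case-insensitively.
    """
    if isinstance(text, (int, float)):
        return to_logmar(VAMeasure.logmar(float(text)), rounding=rounding)
    s = str(text).strip()
    if not s:
        raise ValueError("empty visual-acuity cell")
    if "/" in s:
        num_s, den_s = s.split("/", 1)
        return to_logmar(VAMeasure.snellen(float(num_s), float(den_s)), rounding=rounding)
    if s.upper() in VACategory.__members__:
        return to_logmar(VAMeasure.categorical(s), rounding=rounding)
    return to_logmar(VAMeasure.logmar(float(s)), rounding=rounding)


def classify_va_group(bcva: float, cutoff: float = 0.30) -> str:
    """Assign a logMAR BCVA to the ``good`` or ``poor`` VA group.

    ``good`` means strictly below the cutoff (default 0.30 logMAR, Snellen
    6/12); the boundary itself belongs to the poor group.
    """
    if not math.isfinite(bcva):
        raise ValueError(f"BCVA must be finite, got {bcva}")
    return "good" if bcva < cutoff else "poor"


@dataclass(frozen=True)
class VAPredictionEval:
    """Error statistics for a set of paired predicted/actual logMAR values.

    ``group_sensitivity[g]`` is the share of eyes whose *actual* group is
    ``g`` that were predicted into the same group; ``group_precision[g]``
    conditions on the *predicted* group instead.  A group that never occurs
    in the relevant margin yields ``None`` (undefined), never zero.
    """

    mae: float
    rmse: float
    re_within: float
    group_sensitivity: dict[str, float | None]
    group_precision: dict[str, float | None]
    n: int


def evaluate_predictions(
    predicted: Sequence[float],
    actual: Sequence[float],
    re_threshold: float = 0.30,
    cutoff: float = 0.30,
) -> VAPredictionEval:
    """Evaluate logMAR BCVA predictions against measured ground truth.

    Computes MAE, RMSE, the fraction of predictions within ``re_threshold``
    of the truth (closed interval, so an error of exactly 0.30 counts as
    within), and per-group sensitivity/precision for the good/poor split at
    ``cutoff``.
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape or pred.ndim != 1:
        raise ValueError(
            f"predicted and actual must be equal-length 1-D, got {pred.shape} vs {act.shape}"
        )
    if pred.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if not (np.isfinite(pred).all() and np.isfinite(act).all()):
        raise ValueError("non-finite logMAR value in inputs")

    err = pred - act
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    # closed interval; the epsilon keeps an exactly-boundary error (e.g.
    # |0.4 - 0.1|) inside the band despite binary-float representation
    re_within = float(np.mean(np.abs(err) <= re_threshold + 1e-12))

    pred_good = pred < cutoff
    act_good = act < cutoff
    correct = pred_good == act_good

    sens: dict[str, float | None] = {}
    prec: dict[str, float | None] = {}
    for name, mask in (("good", act_good), ("poor", ~act_good)):
        sens[name] = float(correct[mask].mean()) if mask.any() else None
    for name, mask in (("good", pred_good), ("poor", ~pred_good)):
        prec[name] = float(correct[mask].mean()) if mask.any() else None

    return VAPredictionEval(
        mae=mae,
        rmse=rmse,
        re_within=re_within,
        group_sensitivity=sens,
        group_precision=prec,
        n=int(pred.size),
    )
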