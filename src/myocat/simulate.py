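"""Synthetic highly-myopic-cataract cohorts with known ground truth.

The clinical cohorts behind this kind of triage evaluation are not public,
so the simulator generates per-eye records with the same statistical
structure the evaluation pipeline assumes: a latent gold-standard surgical
category drawn from configurable prevalences, LOCS III grades consistent
with that category, automated grades equal to the gold grades plus a
rounded Gaussian error, a postoperative-acuity prediction with Gaussian
error, OCT findings consistent with the category, axial lengths from a
truncated normal above the 26 mm high-myopia floor, and per-rater
decisions drawn from row-stochastic confusion matrices conditioned on the
gold category.

Default calibration constants reproduce the error levels a well-performing
grader/predictor shows on internal validation: nuclear and cortical
grading-error scales are solved from target Re1.0 values of 99.07% and
88.79% (:func:`calibrate_sigma_from_re10`), and the acuity-prediction
error scale is sigma = MAE / sqrt(2/pi) with MAE = 0.156 logMAR, using the
half-normal mean identity E|N(0, s)| = s*sqrt(2/pi).

Randomness uses one global seed driving named per-eye, per-field
substreams, so adding a field never perturbs existing draws and the same
seed always yields a byte-identical cohort.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .engine import (
    DEFAULT_OCT_SURGICAL_MAP,
    DecisionCategory,
    EyeRecord,
    GradeSet,
)
from .grading import GRADE_RANGES, CataractSubtype

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "calibrate_sigma_from_re10",
    "DEFAULT_RATER_CONFUSION",
]


def calibrate_sigma_from_re10(
    target_re10: float, threshold: float = 1.0, step: float = 0.1
) -> float:
    """Solve for the Gaussian error scale that hits a target Re1.0.

    The grading error is N(0, sigma) rounded to the LOCS III ``step`` of
    0.1, so the rounded error falls within ``threshold`` exactly when the
    raw error is below threshold + step/2.  Bisection solves
    2*Phi((threshold + step/2)/sigma) - 1 = target, to 1e-6 on the
    probability.
    """
    if not (0.0 < target_re10 < 100.0):
        raise ValueError(f"target Re1.0 must be in (0, 100), got {target_re10}")
    p_target = target_re10 / 100.0
    edge = threshold + step / 2.0

    def prob(sigma: float) -> float:
        return 2.0 * stats.norm.cdf(edge / sigma) - 1.0

    lo, hi = 1e-6, 1e6
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if prob(mid) > p_target:
            lo = mid
        else:
            hi = mid
        if abs(prob(mid) - p_target) < 1e-6:
            return mid
    return 0.5 * (lo + hi)


# Internal-validation calibration targets: Re1.0 of 99.07% (nuclear) and
# 88.79% (cortical); acuity-prediction MAE of 0.156 logMAR.
SIGMA_NUCLEAR_DEFAULT = calibrate_sigma_from_re10(99.07)
SIGMA_CORTICAL_DEFAULT = calibrate_sigma_from_re10(88.79)
SIGMA_PRED_DEFAULT = 0.156 / math.sqrt(2.0 / math.pi)

#: Gold-standard category prevalence: 1 no-surgery, 95 cataract, 5 retinal,
#: 6 combined per 107 eyes — the internal-validation case mix.
DEFAULT_PREVALENCE = (1 / 107, 95 / 107, 5 / 107, 6 / 107)


def _row_stochastic(counts: Sequence[Sequence[float]]) -> np.ndarray:
    m = np.asarray(counts, dtype=float)
    return m / m.sum(axis=1, keepdims=True)


#: Default per-rater confusion matrices (row = gold category, column =
#: rater's answer).  Each is a synthetic integer realization consistent
#: with the internal-validation per-category counts and agreement totals of
#: the corresponding rater (the published tables fix only marginals and the
#: diagonal sum, not the full table), then row-normalised.
DEFAULT_RATER_CONFUSION: dict[str, np.ndarray] = {
    "ai": _row_stochastic([[1, 0, 0, 0], [0, 94, 0, 1], [0, 2, 2, 1], [0, 0, 0, 6]]),
    "senior": _row_stochastic([[1, 0, 0, 0], [7, 86, 1, 1], [0, 1, 4, 0], [0, 0, 1, 5]]),
    "junior": _row_stochastic([[1, 0, 0, 0], [7, 86, 1, 1], [0, 1, 4, 0], [0, 0, 1, 5]]),
    "resident": _row_stochastic([[0, 1, 0, 0], [0, 90, 4, 1], [0, 0, 1, 4], [0, 0, 4, 2]]),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the internal-validation
    calibration described in the module docstring."""

    n: int = 107
    class_prevalence: tuple[float, float, float, float] = DEFAULT_PREVALENCE
    sigma_nuclear: float = SIGMA_NUCLEAR_DEFAULT
    sigma_cortical: float = SIGMA_CORTICAL_DEFAULT
    sigma_pred: float = SIGMA_PRED_DEFAULT
    rater_confusion: Mapping[str, np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_RATER_CONFUSION)
    )
    # axial length (mm): truncated normal, floor strictly above 26.0
    al_mean: float = 28.5
    al_sd: float = 1.5
    al_min: float = 26.01
    # postoperative BCVA truth (logMAR): (mean, sd) without / with retinal pathology
    postop_va_clear: tuple[float, float] = (0.12, 0.12)
    postop_va_retinal: tuple[float, float] = (0.75, 0.35)
    # preoperative acuity: good-VA range for no-surgery eyes; cataract-driven
    # acuity loss (mean, sd of the positive gain added to postoperative truth)
    preop_good_range: tuple[float, float] = (0.0, 0.25)
    cataract_gain: tuple[float, float] = (0.55, 0.25)
    # probability that the significant grade of a surgical cataract is nuclear
    p_nuclear_driver: float = 0.8
    # probability of an (unmapped) CNV finding in eyes without surgical pathology
    p_cnv_incidental: float = 0.08
    oct_surgical_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OCT_SURGICAL_MAP)
    )
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.n < 1:
            problems.append(f"n must be >= 1, got {self.n}")
        prev = np.asarray(self.class_prevalence, dtype=float)
        if prev.shape != (4,) or (prev < 0).any() or not math.isclose(prev.sum(), 1.0, abs_tol=1e-9):
            problems.append(f"class_prevalence must be 4 non-negative values summing to 1, got {self.class_prevalence}")
        for name in ("sigma_nuclear", "sigma_cortical", "sigma_pred"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for rater, mat in self.rater_confusion.items():
            m = np.asarray(mat, dtype=float)
            if m.shape != (4, 4) or (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
                problems.append(f"rater_confusion[{rater!r}] must be a 4x4 row-stochastic matrix")
        if self.al_min <= 26.0 - 1e-12:
            problems.append("al_min must exceed the 26.0 mm inclusion floor")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


def _substream(seed: int, eye_index: int, name: str) -> np.random.Generator:
    """Independent generator for one named field of one eye."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, eye_index, zlib.crc32(name.encode())])
    )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return min(max(mean, lo), hi)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _round_grade(x: float, subtype: CataractSubtype) -> float:
    lo, hi = GRADE_RANGES[subtype]
    return float(np.clip(round(x, 1), lo, hi))


_CATARACT_CLASSES = {DecisionCategory.CATARACT_SURGERY, DecisionCategory.COMBINED_SURGERY}
_RETINAL_CLASSES = {DecisionCategory.RETINAL_SURGERY, DecisionCategory.COMBINED_SURGERY}


def _sample_gold_grades(cfg: SimulationConfig, rng: np.random.Generator, cls: DecisionCategory) -> GradeSet:
    n_lo, n_hi = GRADE_RANGES[CataractSubtype.NUCLEAR]
    c_lo, c_hi = GRADE_RANGES[CataractSubtype.CORTICAL]
    thr = 3.5
    if cls in _CATARACT_CLASSES:
        nuclear_driver = rng.random() < cfg.p_nuclear_driver
        if nuclear_driver:
            nuclear = _truncnorm(rng, 4.5, 0.6, thr + 0.1, n_hi)
            cortical = _truncnorm(rng, 2.5, 0.8, c_lo, thr)
        else:
            nuclear = _truncnorm(rng, 2.8, 0.7, n_lo, thr)
            cortical = _truncnorm(rng, 4.2, 0.4, thr + 0.1, c_hi)
    else:
        nuclear = _truncnorm(rng, 2.5, 0.7, n_lo, thr)
        cortical = _truncnorm(rng, 2.0, 0.7, c_lo, thr)
    psc = _truncnorm(rng, 1.5, 0.5, 1.0, 5.0)
    return GradeSet(
        nuclear=_round_grade(nuclear, CataractSubtype.NUCLEAR),
        cortical=_round_grade(cortical, CataractSubtype.CORTICAL),
        psc=_round_grade(psc, CataractSubtype.PSC),
    )


def _perturb_grades(cfg: SimulationConfig, rng: np.random.Generator, gold: GradeSet) -> GradeSet:
    """Automated grades: gold + Gaussian error rounded to the 0.1 step, clipped."""

    def one(value: float, sigma: float, subtype: CataractSubtype) -> float:
        err = round(float(rng.normal(0.0, sigma)), 1) if sigma > 0 else 0.0
        return _round_grade(value + err, subtype)

    return GradeSet(
        nuclear=one(gold.nuclear, cfg.sigma_nuclear, CataractSubtype.NUCLEAR),
        cortical=one(gold.cortical, cfg.sigma_cortical, CataractSubtype.CORTICAL),
        psc=one(gold.psc, cfg.sigma_cortical, CataractSubtype.PSC),
    )


def generate_cohort(config: SimulationConfig | None = None) -> list[EyeRecord]:
    """Generate a fully reproducible synthetic cohort.

    Each record carries gold and automated ("ai") LOCS III grades, true and
    predicted postoperative BCVA, OCT findings, axial length, a
    gold-standard decision equal to the latent category, and one decision
    per configured rater drawn from that rater's confusion row.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    prevalence = np.asarray(cfg.class_prevalence, dtype=float)
    surgical_findings = sorted(
        label for label, target in cfg.oct_surgical_map.items() if target == "retinal_surgery"
    )
    records: list[EyeRecord] = []
    for i in range(cfg.n):
        cls = DecisionCategory(
            int(_substream(cfg.seed, i, "class").choice(4, p=prevalence))
        )

        gold_grades = _sample_gold_grades(cfg, _substream(cfg.seed, i, "gold_grades"), cls)
        ai_grades = _perturb_grades(cfg, _substream(cfg.seed, i, "ai_grades"), gold_grades)

        va_rng = _substream(cfg.seed, i, "postop_va")
        mean, sd = cfg.postop_va_retinal if cls in _RETINAL_CLASSES else cfg.postop_va_clear
        postop_true = _truncnorm(va_rng, mean, sd, -0.3, 3.0)
        predicted = postop_true + float(
            _substream(cfg.seed, i, "pred_error").normal(0.0, cfg.sigma_pred)
        )

        preop_rng = _substream(cfg.seed, i, "preop_va")
        if cls in _CATARACT_CLASSES:
            gain = abs(float(preop_rng.normal(*cfg.cataract_gain)))
            preop = max(0.35, postop_true + gain)
        elif cls == DecisionCategory.RETINAL_SURGERY:
            preop = postop_true + abs(float(preop_rng.normal(0.1, 0.1)))
        else:  # no surgery: good preoperative acuity
            preop = float(preop_rng.uniform(*cfg.preop_good_range))
        preop = float(np.clip(preop, -0.3, 3.0))

        oct_rng = _substream(cfg.seed, i, "oct")
        if cls in _RETINAL_CLASSES:
            findings = (str(oct_rng.choice(surgical_findings)),)
        else:
            findings = ("cnv",) if oct_rng.random() < cfg.p_cnv_incidental else ("none",)

        al = _truncnorm(
            _substream(cfg.seed, i, "axial_length"), cfg.al_mean, cfg.al_sd, cfg.al_min, 36.0
        )

        decisions: dict[str, DecisionCategory] = {"gold": cls}
        for rater in sorted(cfg.rater_confusion):
            row = np.asarray(cfg.rater_confusion[rater], dtype=float)[int(cls)]
            decisions[rater] = DecisionCategory(
                int(_substream(cfg.seed, i, f"decision_{rater}").choice(4, p=row))
            )

        records.append(
            EyeRecord(
                eye_id=f"eye{i:05d}",
                axial_length=round(al, 2),
                preop_bcva=round(preop, 4),
                predicted_postop_bcva=round(predicted, 4),
                actual_postop_bcva=round(postop_true, 4),
                grades={"gold": gold_grades, "ai": ai_grades},
                oct_findings=findings,
                decisions=decisions,
            )
        )
    return records
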