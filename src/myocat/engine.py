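"""Rule-based surgical triage for highly myopic cataract eyes.

One eye's record — preoperative BCVA, predicted postoperative BCVA, LOCS III
cataract grades, macular OCT findings, axial length — is mapped to one of
four recommendations:

* 0 — surgery not advised
* 1 — cataract surgery recommended
* 2 — retinal surgery recommended
* 3 — combined cataract-retinal surgery recommended

The decision runs in at most five steps, in fixed order: (1) preoperative
visual acuity, (2) predicted postoperative improvement, (3) cataract
grading, (4) OCT findings, (5) axial length.  The step order, the four
categories, the grade-above-3.5 surgery rule and the 0.30 logMAR acuity
convention are the fixed skeleton; every branch threshold and the
OCT-finding-to-surgery mapping are configuration, so the rule table can be
re-specified without code changes.  Each decision carries an ordered trace
of the steps actually evaluated, making the applied rule auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import json
import math

import yaml

from .grading import CataractSubtype, LocsGrade, surgical_indication

__all__ = [
    "DecisionCategory",
    "OCT_VOCABULARY",
    "DEFAULT_OCT_SURGICAL_MAP",
    "DecisionConfig",
    "GradeSet",
    "EyeRecord",
    "StepRecord",
    "Decision",
    "decide",
    "batch_decide",
]


class DecisionCategory(IntEnum):
    """Four-level surgical recommendation."""

    NO_SURGERY = 0
    CATARACT_SURGERY = 1
    RETINAL_SURGERY = 2
    COMBINED_SURGERY = 3

    @property
    def label(self) -> str:
        return {
            DecisionCategory.NO_SURGERY: "surgery not advised",
            DecisionCategory.CATARACT_SURGERY: "cataract surgery recommended",
            DecisionCategory.RETINAL_SURGERY: "retinal surgery recommended",
            DecisionCategory.COMBINED_SURGERY: "combined cataract-retinal surgery recommended",
        }[self]


#: Macular OCT finding vocabulary for highly myopic eyes.
OCT_VOCABULARY: tuple[str, ...] = (
    "epiretinal_traction",
    "macular_retinoschisis",
    "retinal_thickening",
    "lamellar_hole",
    "foveal_retinoschisis",
    "foveal_retinal_detachment",
    "cnv",
    "macular_hole",
    "none",
)

#: Default mapping from OCT finding to its surgical implication.  Structural
#: macular pathology maps to retinal surgery; choroidal neovascularization
#: (cnv) maps to none because it is typically managed medically (anti-VEGF),
#: not surgically.  Every entry is overridable in DecisionConfig.
DEFAULT_OCT_SURGICAL_MAP: dict[str, str] = {
    "epiretinal_traction": "retinal_surgery",
    "macular_retinoschisis": "retinal_surgery",
    "retinal_thickening": "retinal_surgery",
    "lamellar_hole": "retinal_surgery",
    "foveal_retinoschisis": "retinal_surgery",
    "foveal_retinal_detachment": "retinal_surgery",
    "cnv": "none",
    "macular_hole": "retinal_surgery",
    "none": "none",
}


@dataclass(frozen=True)
class DecisionConfig:
    """All thresholds and mappings of the five-step rule table.

    preop_va_threshold
        logMAR below which preoperative acuity counts as good (default
        0.30, Snellen 6/12).
    improvement_threshold
        Minimum predicted acuity gain (preop minus predicted postop, in
        logMAR) that counts as a clinically meaningful improvement; default
        0.20 logMAR, about two Snellen lines.
    grade_threshold
        LOCS III grade above which (strictly) cataract surgery is indicated
        (default 3.5, applied to nuclear and cortical grades).
    al_caution_threshold
        Axial length (mm) at or beyond which a significant cataract without
        meaningful predicted gain is not operated (default 30.0 mm).
    oct_surgical_map
        Total mapping from every OCT finding label to ``none`` or
        ``retinal_surgery``.
    """

    preop_va_threshold: float = 0.30
    improvement_threshold: float = 0.20
    grade_threshold: float = 3.5
    al_caution_threshold: float = 30.0
    oct_surgical_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OCT_SURGICAL_MAP)
    )

    def __post_init__(self) -> None:
        for name in (
            "preop_va_threshold",
            "improvement_threshold",
            "grade_threshold",
            "al_caution_threshold",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        bad = {v for v in self.oct_surgical_map.values()} - {"none", "retinal_surgery"}
        if bad:
            raise ValueError(f"invalid OCT surgical mapping targets: {sorted(bad)}")

    def oct_mapping(self, label: str) -> str:
        try:
            return self.oct_surgical_map[label]
        except KeyError:
            raise KeyError(
                f"OCT finding {label!r} has no entry in oct_surgical_map"
            ) from None

    @classmethod
    def from_file(cls, path: str | Path) -> "DecisionConfig":
        """Load a config from YAML or JSON; omitted keys keep defaults."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) if path.suffix in {".yaml", ".yml"} \
            else json.loads(path.read_text())
        raw = raw or {}
        oct_map = dict(DEFAULT_OCT_SURGICAL_MAP)
        oct_map.update(raw.pop("oct_surgical_map", {}))
        return cls(oct_surgical_map=oct_map, **raw)


@dataclass(frozen=True)
class GradeSet:
    """LOCS III grades of one eye from one grader."""

    nuclear: float
    cortical: float
    psc: float

    def __post_init__(self) -> None:
        self.as_locs()  # range-validate against the LOCS III scales

    def as_locs(self) -> tuple[LocsGrade, LocsGrade, LocsGrade]:
        return (
            LocsGrade(CataractSubtype.NUCLEAR, self.nuclear),
            LocsGrade(CataractSubtype.CORTICAL, self.cortical),
            LocsGrade(CataractSubtype.PSC, self.psc),
        )


@dataclass(frozen=True)
class EyeRecord:
    """One eye's full clinical and predicted state.

    ``grades`` maps a grade source ("ai", "gold") to a :class:`GradeSet`;
    ``decisions`` maps a rater id ("gold", "ai", "senior", ...) to that
    rater's :class:`DecisionCategory`.  Cohort inclusion requires axial
    length strictly above 26.0 mm (the operational definition of high
    myopia here); the constructor enforces positivity only, so readers can
    flag rather than drop out-of-criterion rows.
    """

    eye_id: str
    axial_length: float
    preop_bcva: float
    predicted_postop_bcva: float | None
    grades: Mapping[str, GradeSet]
    actual_postop_bcva: float | None = None
    oct_findings: tuple[str, ...] = ("none",)
    decisions: Mapping[str, DecisionCategory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axial_length <= 0:
            raise ValueError(f"axial length must be positive, got {self.axial_length}")
        if not math.isfinite(self.preop_bcva):
            raise ValueError("preoperative BCVA must be finite")

    @property
    def meets_inclusion(self) -> bool:
        """Axial length > 26.0 mm, the high-myopia inclusion criterion."""
        return self.axial_length > 26.0


@dataclass(frozen=True)
class StepRecord:
    step: int
    name: str
    outcome: str


@dataclass(frozen=True)
class Decision:
    category: DecisionCategory
    trace: tuple[StepRecord, ...]


def decide(
    eye: EyeRecord,
    config: DecisionConfig | None = None,
    grade_source: str = "ai",
) -> Decision:
    """Run the five-step rule table on one eye.

    Step 1 — preoperative VA: good preoperative acuity with no surgical
    OCT finding short-circuits to 0 (nothing to gain from surgery).
    Step 2 — improvement: predicted gain = preop minus predicted postop
    BCVA; a gain of at least ``improvement_threshold`` is meaningful.
    Step 3 — grading: cataract is significant when the nuclear or cortical
    grade (from ``grade_source``) strictly exceeds ``grade_threshold``.
    Step 4 — OCT: any finding mapped to retinal surgery yields 3 when the
    cataract is also significant, else 2.
    Step 5 — axial length: a significant cataract with meaningful gain
    yields 1; without meaningful gain it yields 1 only below the
    axial-length caution threshold, else 0.  No significant cataract
    yields 0.
    """
    config = config or DecisionConfig()
    if eye.predicted_postop_bcva is None:
        raise ValueError(
            f"eye {eye.eye_id}: decision requires predicted_postop_bcva "
            "(postoperative acuity prediction missing)"
        )
    if grade_source not in eye.grades:
        raise ValueError(f"eye {eye.eye_id}: no grades from source {grade_source!r}")

    trace: list[StepRecord] = []
    mappings = [config.oct_mapping(f) for f in eye.oct_findings]
    retinal_indicated = "retinal_surgery" in mappings

    # S1: good preop acuity and a quiet macula -> nothing to operate on
    good_preop = eye.preop_bcva < config.preop_va_threshold
    trace.append(StepRecord(1, "preoperative_va", "good" if good_preop else "reduced"))
    if good_preop and not retinal_indicated:
        return Decision(DecisionCategory.NO_SURGERY, tuple(trace))

    improvement = eye.preop_bcva - eye.predicted_postop_bcva
    meaningful_gain = improvement >= config.improvement_threshold
    trace.append(
        StepRecord(
            2,
            "postop_improvement",
            f"gain={improvement:.2f} "
            + ("meaningful" if meaningful_gain else "not meaningful"),
        )
    )

    g = eye.grades[grade_source]
    cataract_significant = surgical_indication(
        g.nuclear, g.cortical, config.grade_threshold
    )
    trace.append(
        StepRecord(
            3,
            "cataract_grading",
            "significant" if cataract_significant else "not significant",
        )
    )

    trace.append(
        StepRecord(4, "oct_findings", "retinal surgery indicated" if retinal_indicated else "no surgical pathology")
    )
    if retinal_indicated:
        cat = (
            DecisionCategory.COMBINED_SURGERY
            if cataract_significant
            else DecisionCategory.RETINAL_SURGERY
        )
        return Decision(cat, tuple(trace))

    if cataract_significant:
        if meaningful_gain:
            cat = DecisionCategory.CATARACT_SURGERY
            outcome = "significant cataract, meaningful gain"
        elif eye.axial_length < config.al_caution_threshold:
            cat = DecisionCategory.CATARACT_SURGERY
            outcome = "significant cataract, AL below caution threshold"
        else:
            cat = DecisionCategory.NO_SURGERY
            outcome = "extreme axial length without predicted gain"
    else:
        cat = DecisionCategory.NO_SURGERY
        outcome = "no significant cataract"
    trace.append(StepRecord(5, "axial_length", outcome))
    return Decision(cat, tuple(trace))


def batch_decide(
    cohort: Iterable[EyeRecord],
    config: DecisionConfig | None = None,
    grade_source: str = "ai",
) -> dict[str, Decision]:
    """Element-wise :func:`decide` over a cohort, keyed by eye id."""
    out: dict[str, Decision] = {}
    for eye in cohort:
        try:
            out[eye.eye_id] = decide(eye, config, grade_source)
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"eye {eye.eye_id}: {exc}") from exc
    return out


def with_decision(eye: EyeRecord, rater: str, category: DecisionCategory) -> EyeRecord:
    """Return a copy of ``eye`` with one rater's decision added."""
    decisions = dict(eye.decisions)
    decisions[rater] = category
    return replace(eye, decisions=decisions)
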