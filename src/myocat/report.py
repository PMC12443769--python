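"""Consolidated evaluation report over one cohort.

Mirrors the standard validation layout for this kind of pipeline: a
grading-performance section per cataract subtype (Re1.0 with its fraction,
ICC, binary diagnostic metrics against the gold surgical flag, AUC with
CI), a postoperative-acuity-prediction section (MAE, RMSE, share within
the 0.30 logMAR band, per-VA-group sensitivity/precision), the decision
distribution per rater, and consistency plus Cohen's kappa per rater
overall and on the special-case subset (gold decision 0, 2 or 3).

Reported precision follows clinical convention: percentages to 2 decimals,
kappa/ICC/AUC to 3, logMAR metrics to 4.  Every percentage carries its
numerator and denominator.  A section whose inputs are missing is skipped
with an explicit reason, never silently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import json

import numpy as np

from . import agreement, grading, va
from .agreement import round_half_up
from .engine import DecisionConfig, EyeRecord, batch_decide

__all__ = ["run_report", "write_report"]


def _pct(numerator: int, denominator: int) -> dict:
    return {
        "pct": round(100.0 * numerator / denominator, 2),
        "numerator": numerator,
        "denominator": denominator,
    }


def _grading_section(records: Sequence[EyeRecord], config: DecisionConfig) -> dict:
    # Each subtype is scored against its own surgical threshold (grade
    # strictly above config.grade_threshold), so nuclear and cortical
    # columns carry independent diagnostic metrics; the ROC score is the
    # continuous automated grade of that subtype.
    section: dict = {}
    for subtype in ("nuclear", "cortical"):
        ai = np.array([getattr(r.grades["ai"], subtype) for r in records])
        gold = np.array([getattr(r.grades["gold"], subtype) for r in records])
        errors = np.abs(ai - gold)
        n = len(records)
        within = int((errors <= 1.0).sum())
        icc = grading.icc_absolute(list(zip(ai, gold)))
        gold_flags = list(gold > config.grade_threshold)
        pred_flags = list(ai > config.grade_threshold)
        bm = grading.binary_metrics(pred_flags, gold_flags)
        entry = {
            "re10": _pct(within, n),
            "icc": None if icc.value is None else round_half_up(icc.value, 3),
            "accuracy": round(bm.accuracy, 4),
            "sensitivity": None if bm.sensitivity is None else round(bm.sensitivity, 4),
            "specificity": None if bm.specificity is None else round(bm.specificity, 4),
            "n": n,
        }
        if len(set(gold_flags)) == 2:
            auc, (lo, hi) = grading.auc_confidence_interval(ai, gold_flags)
            entry["auc"] = round_half_up(auc, 3)
            entry["auc_ci"] = [round_half_up(lo, 3), round_half_up(hi, 3)]
        else:
            entry["auc"] = None
            entry["auc_skipped_reason"] = "gold surgical flag is single-class"
        section[subtype] = entry
    return section


def _va_section(records: Sequence[EyeRecord]) -> dict:
    paired = [
        (r.predicted_postop_bcva, r.actual_postop_bcva)
        for r in records
        if r.actual_postop_bcva is not None and r.predicted_postop_bcva is not None
    ]
    if not paired:
        return {"skipped_reason": "no eyes with actual postoperative BCVA"}
    pred, act = zip(*paired)
    ev = va.evaluate_predictions(pred, act)
    return {
        "mae": round(ev.mae, 4),
        "rmse": round(ev.rmse, 4),
        "re_within_0.30": _pct(int(round(ev.re_within * ev.n)), ev.n),
        "sensitivity": {
            g: (None if v is None else round(v, 4)) for g, v in ev.group_sensitivity.items()
        },
        "precision": {
            g: (None if v is None else round(v, 4)) for g, v in ev.group_precision.items()
        },
        "n": ev.n,
    }


def _agreement_entry(gold: list[int], comp: list[int]) -> dict:
    matrix = agreement.build_confusion(gold, comp)
    res = agreement.cohen_kappa(matrix)
    return {
        "consistency": _pct(res.agree_count, res.n),
        "kappa": res.kappa_reported,
        "po": round(res.po, 4),
        "pe": round(res.pe, 4),
        "confusion": matrix.counts.tolist(),
    }


def run_report(
    records: Sequence[EyeRecord],
    config: DecisionConfig | None = None,
    raters: Sequence[str] | None = None,
    heatmap_dir: str | Path | None = None,
) -> dict:
    """Compute the full evaluation report as a JSON-serialisable dict.

    ``raters`` defaults to every rater present in the records other than
    the gold standard; the engine's own decisions are evaluated as rater
    ``"engine"`` whenever AI grades and predictions are available.
    """
    config = config or DecisionConfig()
    if not records:
        raise ValueError("cannot report on an empty cohort")
    report: dict = {"n": len(records)}

    report["grading"] = _grading_section(records, config)
    report["va_prediction"] = _va_section(records)

    with_gold = [r for r in records if "gold" in r.decisions]
    if not with_gold:
        report["decisions"] = {"skipped_reason": "no gold-standard decisions in cohort"}
        return report

    gold = [int(r.decisions["gold"]) for r in with_gold]
    if raters is None:
        raters = [r for r in {k for rec in with_gold for k in rec.decisions} if r != "gold"]
        raters = sorted(raters)

    decisions_section: dict = {
        "gold_distribution": [int(x) for x in np.bincount(gold, minlength=4)],
        "raters": {},
    }
    special = agreement.special_case_subset(with_gold)
    special_ids = {r.eye_id for r in special}

    comparator_lists: dict[str, list[int]] = {}
    for rater in raters:
        if not all(rater in r.decisions for r in with_gold):
            decisions_section["raters"][rater] = {
                "skipped_reason": f"rater {rater!r} missing decisions for some eyes"
            }
            continue
        comparator_lists[rater] = [int(r.decisions[rater]) for r in with_gold]

    engine_decisions = batch_decide(with_gold, config, grade_source="ai")
    comparator_lists["engine"] = [int(engine_decisions[r.eye_id].category) for r in with_gold]

    for rater, comp in comparator_lists.items():
        entry = {
            "distribution": [int(x) for x in np.bincount(comp, minlength=4)],
            "overall": _agreement_entry(gold, comp),
        }
        if special:
            mask = [r.eye_id in special_ids for r in with_gold]
            entry["special_cases"] = _agreement_entry(
                [g for g, m in zip(gold, mask) if m], [c for c, m in zip(comp, mask) if m]
            )
            entry["special_cases"]["n_special"] = len(special)
        else:
            entry["special_cases"] = {"skipped_reason": "no special-case eyes (gold 0/2/3)"}
        decisions_section["raters"][rater] = entry

        if heatmap_dir is not None:
            matrix = agreement.build_confusion(gold, comp)
            img, csv_path = agreement.heatmap_export(
                matrix,
                Path(heatmap_dir) / f"heatmap_{rater}.png",
                title=f"{rater} vs gold standard (n={matrix.n})",
                comparator_label=rater,
            )
            decisions_section["raters"][rater]["heatmap"] = str(img)
            decisions_section["raters"][rater]["heatmap_csv"] = str(csv_path)

    report["decisions"] = decisions_section
    return report


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path
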