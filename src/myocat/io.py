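"""Cohort file I/O: a flat CSV/JSON schema round-trippable with EyeRecord.

One row per eye.  Visual-acuity cells accept any of the notations the
parser understands ("6/12", "0.30", "CF", "hm", ...) and are normalised to
logMAR on load.  Decision columns are ``decision_<rater>`` with values in
0..3; the gold standard is ``decision_gold``.  OCT findings are a
semicolon-joined list.  Simulated and real cohorts share this schema, so
they are interchangeable everywhere downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .engine import DecisionCategory, EyeRecord, GradeSet
from .va import parse_va

__all__ = ["CohortTable", "read_cohort", "write_cohort", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "eye_id",
    "axial_length",
    "preop_bcva",
    "predicted_postop_bcva",
    "nuclear_ai",
    "cortical_ai",
    "psc_ai",
    "nuclear_gold",
    "cortical_gold",
    "psc_gold",
)

OPTIONAL_COLUMNS = ("actual_postop_bcva", "oct_findings")


@dataclass
class CohortTable:
    """Validated cohort with provenance and any per-row problems collected."""

    records: list[EyeRecord]
    source: str
    warnings: list[str] = field(default_factory=list)
    row_errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def raters(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            for rater in r.decisions:
                seen.setdefault(rater, None)
        return list(seen)


def _record_from_row(row: dict, line: int, warnings: list[str]) -> EyeRecord:
    eye_id = str(row["eye_id"])
    al = float(row["axial_length"])
    if al <= 26.0:
        warnings.append(
            f"line {line}: eye {eye_id} axial_length {al} mm does not meet the "
            "high-myopia inclusion criterion (> 26.0 mm)"
        )
    grades = {
        source: GradeSet(
            nuclear=float(row[f"nuclear_{source}"]),
            cortical=float(row[f"cortical_{source}"]),
            psc=float(row[f"psc_{source}"]),
        )
        for source in ("ai", "gold")
    }
    oct_raw = row.get("oct_findings")
    if oct_raw is None or (isinstance(oct_raw, float) and pd.isna(oct_raw)) or str(oct_raw).strip() == "":
        findings: tuple[str, ...] = ("none",)
    else:
        findings = tuple(s.strip() for s in str(oct_raw).split(";") if s.strip())

    decisions: dict[str, DecisionCategory] = {}
    for key, value in row.items():
        if key.startswith("decision_") and value is not None and str(value).strip() != "":
            if isinstance(value, float) and pd.isna(value):
                continue
            decisions[key[len("decision_"):]] = DecisionCategory(int(float(value)))

    actual = row.get("actual_postop_bcva")
    has_actual = actual is not None and not (isinstance(actual, float) and pd.isna(actual)) and str(actual).strip() != ""
    return EyeRecord(
        eye_id=eye_id,
        axial_length=al,
        preop_bcva=parse_va(row["preop_bcva"]),
        predicted_postop_bcva=parse_va(row["predicted_postop_bcva"]),
        actual_postop_bcva=parse_va(actual) if has_actual else None,
        grades=grades,
        oct_findings=findings,
        decisions=decisions,
    )


def read_cohort(path: str | Path, format: str | None = None) -> CohortTable:
    """Read and validate a cohort CSV or JSON file.

    Malformed rows are collected into ``row_errors`` with line numbers
    rather than aborting the whole load; schema-level problems (missing
    required columns, duplicate eye ids) raise immediately.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"eye_id": str})
    elif fmt == "json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    if df["eye_id"].duplicated().any():
        dupes = df.loc[df["eye_id"].duplicated(), "eye_id"].tolist()
        raise ValueError(f"{path}: duplicate eye_id values: {dupes}")

    table = CohortTable(records=[], source=str(path))
    for idx, row in enumerate(df.to_dict(orient="records")):
        line = idx + 2  # header is line 1
        try:
            table.records.append(_record_from_row(row, line, table.warnings))
        except (ValueError, KeyError) as exc:
            table.row_errors.append(f"line {line}: {exc}")
    return table


def cohort_to_dataframe(records: Sequence[EyeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "eye_id": r.eye_id,
            "axial_length": r.axial_length,
            "preop_bcva": r.preop_bcva,
            "predicted_postop_bcva": r.predicted_postop_bcva,
            "actual_postop_bcva": r.actual_postop_bcva,
            "nuclear_ai": r.grades["ai"].nuclear,
            "cortical_ai": r.grades["ai"].cortical,
            "psc_ai": r.grades["ai"].psc,
            "nuclear_gold": r.grades["gold"].nuclear,
            "cortical_gold": r.grades["gold"].cortical,
            "psc_gold": r.grades["gold"].psc,
            "oct_findings": ";".join(r.oct_findings),
        }
        for rater, dec in r.decisions.items():
            row[f"decision_{rater}"] = int(dec)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[EyeRecord], path: str | Path, format: str | None = None) -> Path:
    """Write a cohort to CSV or JSON (deterministic given the records)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    df = cohort_to_dataframe(records)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
    return path
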