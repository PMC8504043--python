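"""CSV readers and writers for the package's external interfaces.

Dialect: comma-separated, UTF-8, mandatory header row.  Booleans are written
as ``true``/``false``; a tri-state field that is not applicable is written
as an empty cell and read back as ``None``.  A required boolean left empty
is a validation error, never silently coerced to ``False``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd

from .criteria import AssessmentResult, CriterionOutcome
from .prescriptions import PatientRecord, Prescription

__all__ = [
    "read_prescriptions",
    "read_patients",
    "write_prescriptions",
    "write_patients",
    "write_assessments",
    "write_scores",
]

_RX_BOOL = [
    "as_needed", "trade_name_complete", "active_substances_fully_named",
    "dosage_form_and_release_documented", "is_valid", "is_legible",
    "body_site_required", "complete_and_unambiguous",
]
_RX_TRISTATE = [
    "contains_substance_abbreviation", "dose_strength_documented",
    "single_dose_unit_documented", "dosage_interval_documented",
    "risky_route_stated_unabbreviated", "body_site_documented",
    "reason_documented",
]
_PAT_BOOL = [
    "allergies_documented", "age_documented", "weight_documented",
    "renal_function_documented",
]
_PAT_TRISTATE = ["drug_history_documented"]

_OUTCOME_CODE = {
    CriterionOutcome.MET: "M",
    CriterionOutcome.NOT_MET: "N",
    CriterionOutcome.NOT_APPLICABLE: "X",
}


def _parse_bool(value, column: str, row, required: bool):
    if pd.isna(value) or value == "":
        if required:
            raise ValueError(f"row {row}: required boolean {column!r} is empty")
        return None
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in ("true", "1"):
        return True
    if token in ("false", "0"):
        return False
    raise ValueError(f"row {row}: cannot parse boolean {column!r} from {value!r}")


def read_prescriptions(path: str | Path) -> list[Prescription]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if df.empty:
        raise ValueError(f"{path}: no prescription rows")
    out = []
    for i, row in df.iterrows():
        kwargs = {
            "prescription_id": row["prescription_id"],
            "patient_id": row["patient_id"],
            "route": row["route"],
            "source": row["source"],
            "drug_display_name": row.get("drug_display_name") or "",
            "risk_flags": int(row["risk_flags"]),
            "single_dose_value": (
                None if pd.isna(row.get("single_dose_value"))
                else float(row["single_dose_value"])
            ),
        }
        for col in _RX_BOOL:
            kwargs[col] = _parse_bool(row.get(col), col, i, required=True)
        for col in _RX_TRISTATE:
            kwargs[col] = _parse_bool(row.get(col), col, i, required=False)
        out.append(Prescription(**kwargs))
    return out


def read_patients(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if df.empty:
        raise ValueError(f"{path}: no patient rows")
    out = []
    for i, row in df.iterrows():
        kwargs = {
            "patient_id": row["patient_id"],
            "ward_id": int(row["ward_id"]),
            "time_point": row["time_point"],
            "n_comedications": int(row["n_comedications"]),
            "age_years": None if pd.isna(row.get("age_years")) else int(float(row["age_years"])),
            "sex": row.get("sex") if not pd.isna(row.get("sex")) else None,
            "weight_kg": None if pd.isna(row.get("weight_kg")) else float(row["weight_kg"]),
        }
        for col in _PAT_BOOL:
            kwargs[col] = _parse_bool(row.get(col), col, i, required=True)
        for col in _PAT_TRISTATE:
            kwargs[col] = _parse_bool(row.get(col), col, i, required=False)
        out.append(PatientRecord(**kwargs))
    return out


def _fmt(value):
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if hasattr(value, "value"):  # enums
        return value.value
    return value


def _dataclass_frame(items: Sequence) -> pd.DataFrame:
    rows = [
        {k: _fmt(v) for k, v in dataclasses.asdict(item).items()} for item in items
    ]
    return pd.DataFrame(rows)


def write_prescriptions(prescriptions: Sequence[Prescription], path: str | Path) -> None:
    _dataclass_frame(prescriptions).to_csv(path, index=False)


def write_patients(patients: Sequence[PatientRecord], path: str | Path) -> None:
    _dataclass_frame(patients).to_csv(path, index=False)


def write_assessments(results: Sequence[AssessmentResult], path: str | Path) -> None:
    """One row per prescription; criterion columns coded M/N/X
    (met / not met / not applicable)."""
    rows = []
    for r in results:
        row = {"prescription_id": r.prescription_id,
               "ruleset_version": r.ruleset_version}
        for i, o in enumerate(r.outcomes, start=1):
            row[f"criterion_{i:02d}"] = _OUTCOME_CODE[o]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)
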