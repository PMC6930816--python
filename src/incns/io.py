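"""Long-format observation CSV, outcomes CSV and report JSON.

Observation schema: ``patient_id, timestamp (ISO-8601), variable,
value``. One row per measured variable; a ``variable == "admission"``
row marks N-ICU admission (otherwise the patient's earliest timestamp
is used). Outcomes schema: ``patient_id, mrs_3month``.
"""

from __future__ import annotations

import json
from dataclasses import fields as dc_fields
from datetime import datetime
from pathlib import Path
from typing import Iterable

import pandas as pd

from .comparators import AdmissionType, ComparatorInputs, SapsChronic
from .scoresheet import (
    Arousal,
    Awareness,
    MotorMode,
    MotorPain,
    ReflexResponse,
    Swallow,
    VentInteraction,
    Verbal,
)
from .valstats import OutcomeRecord
from .windowing import ObservationSeries

__all__ = [
    "read_observations",
    "write_observations",
    "read_outcomes",
    "write_outcomes",
    "ObservationFormatError",
]

ADMISSION_VARIABLE = "admission"

_ENUM_FIELDS = {
    "arousal": Arousal,
    "awareness": Awareness,
    "pupillary_reflex": ReflexResponse,
    "corneal_reflex": ReflexResponse,
    "verbal": Verbal,
    "motor_mode": MotorMode,
    "motor_pain": MotorPain,
    "swallow": Swallow,
    "vent_interaction": VentInteraction,
    "admission_type": AdmissionType,
    "saps_chronic": SapsChronic,
}
_BOOL_FIELDS = {
    "intubated",
    "motor_strength_unilateral_low",
    "acute_renal_failure",
    "severe_chronic_condition",
}
_INT_FIELDS = {
    "age",
    "heart_rate",
    "sbp",
    "resp_rate",
    "motor_strength_worst",
    "gcs_eye",
    "gcs_verbal",
    "gcs_motor",
    "four_eye",
    "four_motor",
    "four_brainstem",
    "four_respiration",
}
_ALL_FIELDS = {f.name for f in dc_fields(ComparatorInputs)}
_FLOAT_FIELDS = _ALL_FIELDS - set(_ENUM_FIELDS) - _BOOL_FIELDS - _INT_FIELDS


class ObservationFormatError(ValueError):
    """Schema violation, reported with the offending CSV row number."""


def _parse_value(variable: str, raw: str, row: int):
    if variable in _ENUM_FIELDS:
        try:
            return _ENUM_FIELDS[variable](raw)
        except ValueError:
            raise ObservationFormatError(
                f"row {row}: invalid token {raw!r} for variable {variable!r}"
            ) from None
    if variable in _BOOL_FIELDS:
        low = raw.strip().lower()
        if low in ("true", "1"):
            return True
        if low in ("false", "0"):
            return False
        raise ObservationFormatError(f"row {row}: invalid boolean {raw!r} for {variable!r}")
    try:
        num = float(raw)
    except ValueError:
        raise ObservationFormatError(
            f"row {row}: invalid number {raw!r} for variable {variable!r}"
        ) from None
    return int(round(num)) if variable in _INT_FIELDS else num


def _serialize_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if hasattr(v, "value") and not isinstance(v, (int, float)):
        return str(v.value)
    return repr(v) if isinstance(v, float) else str(v)


def read_observations(path) -> list[ObservationSeries]:
    """Parse an observation CSV into per-patient series.

    Raises :class:`ObservationFormatError` with row-level diagnostics on
    unknown variables, bad tokens, unparseable timestamps or duplicate
    (patient, time, variable) rows.
    """
    df = pd.read_csv(path, dtype=str)
    expected = ["patient_id", "timestamp", "variable", "value"]
    if list(df.columns) != expected:
        raise ObservationFormatError(
            f"expected columns {expected}, found {list(df.columns)}"
        )

    per_patient: dict[str, dict] = {}
    seen: set[tuple] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        pid, ts_raw, variable, raw = row
        if pd.isna(pid) or pd.isna(ts_raw) or pd.isna(variable):
            raise ObservationFormatError(f"row {pos}: missing patient_id/timestamp/variable")
        try:
            ts = datetime.fromisoformat(str(ts_raw))
        except ValueError:
            raise ObservationFormatError(
                f"row {pos}: unparseable timestamp {ts_raw!r}"
            ) from None
        key = (pid, ts, variable)
        if key in seen:
            raise ObservationFormatError(
                f"row {pos}: duplicate observation ({pid}, {ts_raw}, {variable})"
            )
        seen.add(key)
        entry = per_patient.setdefault(pid, {"admission": None, "records": {}})
        if variable == ADMISSION_VARIABLE:
            entry["admission"] = ts
            continue
        if variable not in _ALL_FIELDS:
            raise ObservationFormatError(f"row {pos}: unknown variable {variable!r}")
        if pd.isna(raw):
            raise ObservationFormatError(f"row {pos}: missing value for {variable!r}")
        entry["records"].setdefault(ts, {})[variable] = _parse_value(variable, str(raw), pos)

    series = []
    for pid, entry in per_patient.items():
        if not entry["records"]:
            raise ObservationFormatError(f"patient {pid}: no observations")
        admission = entry["admission"] or min(entry["records"])
        records = tuple(sorted(entry["records"].items()))
        series.append(
            ObservationSeries(patient_id=pid, admission_time=admission, records=records)
        )
    series.sort(key=lambda s: s.patient_id)
    return series


def write_observations(series: Iterable[ObservationSeries], path) -> None:
    rows = []
    for s in series:
        rows.append(
            {
                "patient_id": s.patient_id,
                "timestamp": s.admission_time.isoformat(),
                "variable": ADMISSION_VARIABLE,
                "value": "1",
            }
        )
        for ts, values in s.records:
            for variable in sorted(values):
                rows.append(
                    {
                        "patient_id": s.patient_id,
                        "timestamp": ts.isoformat(),
                        "variable": variable,
                        "value": _serialize_value(values[variable]),
                    }
                )
    pd.DataFrame(rows, columns=["patient_id", "timestamp", "variable", "value"]).to_csv(
        path, index=False
    )


def read_outcomes(path) -> list[OutcomeRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if not {"patient_id", "mrs_3month"}.issubset(df.columns):
        raise ObservationFormatError("outcomes CSV needs patient_id and mrs_3month columns")
    return [
        OutcomeRecord(patient_id=str(r.patient_id), mrs_3month=int(r.mrs_3month))
        for r in df.itertuples(index=False)
    ]


def write_outcomes(outcomes: Iterable[OutcomeRecord], path) -> None:
    pd.DataFrame(
        [{"patient_id": o.patient_id, "mrs_3month": o.mrs_3month} for o in outcomes]
    ).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
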