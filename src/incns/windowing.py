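"""Worst-value abstraction of longitudinal observations.

A patient's time-stamped readings are reduced to one snapshot per
(window, score): for every variable independently, the reading inside
[admission, admission + window] that maximizes that variable's item
points under the chosen score is selected (ties broken by the earliest
qualifying reading). Because variables are maximized independently the
assembled snapshot may mix timestamps — this is how worst-value
severity scores are conventionally abstracted, and a single snapshot
never mixes inconsistent values for one composite item (motor,
respiration and oxygenation travel as groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence, Union

from . import comparators
from .comparators import ComparatorInputs, VariableGroup, score_four, score_gcs
from .scoresheet import (
    Item,
    MissingDataError,
    MotorMode,
    PatientSnapshot,
    Verbal,
    score_incns,
    score_item,
    score_motor,
    score_respiration,
)

__all__ = ["ObservationSeries", "worst_snapshot", "score_series", "INCNS_GROUPS", "SCORE_GROUPS"]

WINDOWS = (24, 72)


@dataclass(frozen=True)
class ObservationSeries:
    """All readings of one patient, as (timestamp, {field: value}) pairs."""

    patient_id: str
    admission_time: datetime
    records: tuple

    def __post_init__(self):
        for t, _ in self.records:
            if t < self.admission_time:
                raise ValueError(
                    f"{self.patient_id}: record at {t} precedes admission "
                    f"{self.admission_time}"
                )


# --------------------------------------------------------------------------
# INCNS variable groups


def _simple_item_group(item: Item, field: str) -> VariableGroup:
    def ev(values: Mapping):
        v = values.get(field)
        if v is None:
            return None
        return score_item(item, v).points, {field: v}

    return VariableGroup(name=item.value, fields=(field,), evaluate=ev)


def _incns_verbal(values: Mapping):
    # an intubated reading scores incomprehensible/none regardless of any
    # recorded verbal value
    if values.get("intubated") is True:
        return 2, {"verbal": Verbal.INCOMPREHENSIBLE_NONE}
    v = values.get("verbal")
    if v is None:
        return None
    return score_item(Item.VERBAL, v).points, {"verbal": v}


def _incns_motor(values: Mapping):
    mode = values.get("motor_mode")
    if mode is None:
        return None
    if mode is MotorMode.STRENGTH_TEST or mode == "strength_test":
        snap_fields = {
            "motor_mode": MotorMode.STRENGTH_TEST,
            "motor_strength_worst": values.get("motor_strength_worst"),
            "motor_strength_unilateral_low": values.get("motor_strength_unilateral_low"),
        }
    else:
        snap_fields = {
            "motor_mode": MotorMode.PAIN_RESPONSE,
            "motor_pain": values.get("motor_pain"),
        }
    try:
        pts = score_motor(PatientSnapshot(**snap_fields)).points
    except MissingDataError:
        return None
    return pts, {k: v for k, v in snap_fields.items() if v is not None}


def _incns_respiration(values: Mapping):
    intubated = values.get("intubated")
    if intubated is None:
        return None
    if intubated:
        snap_fields = {"intubated": True, "vent_interaction": values.get("vent_interaction")}
    else:
        snap_fields = {"intubated": False, "resp_rate": values.get("resp_rate")}
    try:
        pts = score_respiration(PatientSnapshot(**snap_fields)).points
    except MissingDataError:
        return None
    return pts, {k: v for k, v in snap_fields.items() if v is not None}


INCNS_GROUPS: tuple[VariableGroup, ...] = tuple(
    [
        _simple_item_group(Item.WBC, "wbc"),
        _simple_item_group(Item.TEMPERATURE, "temperature_ax"),
        _simple_item_group(Item.ALBUMIN, "albumin"),
        _simple_item_group(Item.AROUSAL, "arousal"),
        _simple_item_group(Item.AWARENESS, "awareness"),
        _simple_item_group(Item.PUPILLARY_REFLEX, "pupillary_reflex"),
        _simple_item_group(Item.CORNEAL_REFLEX, "corneal_reflex"),
        VariableGroup("verbal", ("verbal", "intubated"), _incns_verbal),
        VariableGroup(
            "motor",
            ("motor_mode", "motor_strength_worst", "motor_strength_unilateral_low", "motor_pain"),
            _incns_motor,
        ),
        _simple_item_group(Item.SWALLOW, "swallow"),
        VariableGroup(
            "respiration", ("intubated", "resp_rate", "vent_interaction"), _incns_respiration
        ),
        _simple_item_group(Item.AGE, "age"),
        _simple_item_group(Item.HEART_RATE, "heart_rate"),
        _simple_item_group(Item.SBP, "sbp"),
        _simple_item_group(Item.GLUCOSE, "glucose"),
        _simple_item_group(Item.SODIUM, "sodium"),
        _simple_item_group(Item.POTASSIUM, "potassium"),
        _simple_item_group(Item.CREATININE, "creatinine"),
        _simple_item_group(Item.BILIRUBIN, "bilirubin"),
    ]
)

SCORE_GROUPS: dict[str, tuple[VariableGroup, ...]] = {
    "incns": INCNS_GROUPS,
    "gcs": comparators.GCS_GROUPS,
    "four": comparators.FOUR_GROUPS,
    "apache2": comparators.APACHE2_GROUPS,
    "saps2": comparators.SAPS2_GROUPS,
}


def _canonical_key(t: datetime, values: Mapping) -> tuple:
    # deterministic ordering even for simultaneous readings
    return (t, tuple(sorted((k, repr(v)) for k, v in values.items())))


def worst_snapshot(
    series: ObservationSeries,
    window_hours: int,
    score: str = "incns",
    assume_normal: bool = False,
) -> Union[PatientSnapshot, ComparatorInputs]:
    """Assemble the most-deranged snapshot for one window and score.

    The window is closed: a reading at exactly admission + window counts.
    Raises :class:`MissingDataError` naming every variable with no
    assessable in-window reading, unless ``assume_normal``.
    """
    if window_hours not in WINDOWS:
        raise ValueError(f"window_hours must be one of {WINDOWS}, got {window_hours}")
    if not series.records:
        raise ValueError(f"{series.patient_id}: empty observation series")
    groups = SCORE_GROUPS.get(score)
    if groups is None:
        raise ValueError(f"unknown score {score!r}; expected one of {sorted(SCORE_GROUPS)}")

    cutoff = series.admission_time + timedelta(hours=window_hours)
    in_window = sorted(
        (r for r in series.records if r[0] <= cutoff),
        key=lambda r: _canonical_key(*r),
    )

    assignments: dict = {}
    missing: list[str] = []
    for g in groups:
        best: Optional[tuple[int, dict]] = None
        for _, values in in_window:
            res = g.evaluate(values)
            if res is not None and (best is None or res[0] > best[0]):
                best = res
        if best is None:
            if not assume_normal:
                missing.append(g.name)
            continue
        assignments.update(best[1])
    if missing:
        raise MissingDataError(missing)

    cls = PatientSnapshot if score == "incns" else ComparatorInputs
    return cls(**assignments)


_GCS_BEST = {"gcs_eye": 4, "gcs_verbal": 5, "gcs_motor": 6}
_FOUR_BEST = {"four_eye": 4, "four_motor": 4, "four_brainstem": 4, "four_respiration": 4}


def score_series(
    series: ObservationSeries,
    window_hours: int,
    score: str = "incns",
    assume_normal: bool = False,
):
    """Windowed total for one patient.

    Returns ``(total, snapshot, detail)``; ``detail`` is the
    :class:`~incns.scoresheet.INCNSResult` for INCNS and ``None`` for
    the comparators.
    """
    snap = worst_snapshot(series, window_hours, score, assume_normal)
    if score == "incns":
        result = score_incns(snap, assume_normal=assume_normal)
        return result.total, snap, result
    if score == "gcs":
        comp = {k: getattr(snap, k) if getattr(snap, k) is not None else best
                for k, best in _GCS_BEST.items()}
        return score_gcs(comp["gcs_eye"], comp["gcs_verbal"], comp["gcs_motor"]), snap, None
    if score == "four":
        comp = {k: getattr(snap, k) if getattr(snap, k) is not None else best
                for k, best in _FOUR_BEST.items()}
        return (
            score_four(
                comp["four_eye"], comp["four_motor"], comp["four_brainstem"], comp["four_respiration"]
            ),
            snap,
            None,
        )
    if score == "apache2":
        return comparators.score_apache2(snap, assume_normal=assume_normal), snap, None
    return comparators.score_saps2(snap, assume_normal=assume_normal), snap, None
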