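"""Benchmark severity scores: GCS, FOUR, APACHE II and SAPS II.

APACHE II and SAPS II point tables are transcribed from their original
publications; an independent JSON transcription is bundled under
``resources/`` and a test asserts the two agree cell by cell.

Each score is organised as a list of :class:`VariableGroup` objects: a
named set of input fields plus a function that turns one reading's
values into that variable's points. The windowing module reuses these
groups to pick the most deranged reading per variable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional

from .scoresheet import (
    MissingDataError,
    PatientSnapshot,
    _round_to,
)

__all__ = [
    "AdmissionType",
    "SapsChronic",
    "ComparatorInputs",
    "VariableGroup",
    "score_gcs",
    "score_four",
    "score_apache2",
    "score_saps2",
    "APACHE2_GROUPS",
    "SAPS2_GROUPS",
    "GCS_GROUPS",
    "FOUR_GROUPS",
]

MMOL_CREATININE_PER_MGDL = 88.4


class AdmissionType(str, enum.Enum):
    SCHEDULED_SURGICAL = "scheduled_surgical"
    UNSCHEDULED_SURGICAL = "unscheduled_surgical"
    MEDICAL = "medical"


class SapsChronic(str, enum.Enum):
    NONE = "none"
    METASTATIC_CANCER = "metastatic_cancer"
    HEMATOLOGIC_MALIGNANCY = "hematologic_malignancy"
    AIDS = "aids"


@dataclass(frozen=True, kw_only=True)
class ComparatorInputs(PatientSnapshot):
    """PatientSnapshot extended with the fields only the comparator
    scores need (blood gas, renal, chronic health, GCS/FOUR components).

    For comparator scoring ``resp_rate`` may be present together with
    ``intubated=True`` (APACHE II counts the rate whether or not the
    patient is ventilated); the mutual-exclusion rule applies to the
    INCNS respiration item only.
    """

    map_pressure: Optional[float] = None          # mean arterial pressure, mm Hg
    fio2: Optional[float] = None                  # fraction, 0.21-1.0
    pao2: Optional[float] = None                  # mm Hg
    paco2: Optional[float] = None                 # mm Hg
    aado2: Optional[float] = None                 # mm Hg, overrides computation
    arterial_ph: Optional[float] = None
    hco3: Optional[float] = None                  # mmol/L
    hematocrit: Optional[float] = None            # %
    urine_output_24h: Optional[float] = None      # mL / 24 h
    bun: Optional[float] = None                   # mg/dL
    acute_renal_failure: Optional[bool] = None
    severe_chronic_condition: Optional[bool] = None
    admission_type: Optional[AdmissionType] = None
    saps_chronic: Optional[SapsChronic] = None
    gcs_eye: Optional[int] = None
    gcs_verbal: Optional[int] = None
    gcs_motor: Optional[int] = None
    four_eye: Optional[int] = None
    four_motor: Optional[int] = None
    four_brainstem: Optional[int] = None
    four_respiration: Optional[int] = None

    _allow_resp_rate_when_intubated = True

    def __post_init__(self):
        super().__post_init__()
        for name, lo, hi in (
            ("gcs_eye", 1, 4),
            ("gcs_verbal", 1, 5),
            ("gcs_motor", 1, 6),
            ("four_eye", 0, 4),
            ("four_motor", 0, 4),
            ("four_brainstem", 0, 4),
            ("four_respiration", 0, 4),
        ):
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")


# --------------------------------------------------------------------------
# GCS / FOUR


def score_gcs(eye: int, verbal: int, motor: int) -> int:
    """Glasgow Coma Scale total (3-15)."""
    for name, v, lo, hi in (("eye", eye, 1, 4), ("verbal", verbal, 1, 5), ("motor", motor, 1, 6)):
        if not lo <= v <= hi:
            raise ValueError(f"GCS {name} component must be in [{lo}, {hi}], got {v}")
    return eye + verbal + motor


def score_four(eye: int, motor: int, brainstem: int, respiration: int) -> int:
    """FOUR score total (0-16)."""
    for name, v in (("eye", eye), ("motor", motor), ("brainstem", brainstem), ("respiration", respiration)):
        if not 0 <= v <= 4:
            raise ValueError(f"FOUR {name} component must be in [0, 4], got {v}")
    return eye + motor + brainstem + respiration


# --------------------------------------------------------------------------
# binned lookup shared by APACHE II / SAPS II code tables


def _binned(value: float, precision: int, bins) -> int:
    v = _round_to(value, precision)
    for lo, hi, pts in bins:
        from decimal import Decimal

        if (lo is None or v >= Decimal(repr(lo))) and (hi is None or v <= Decimal(repr(hi))):
            return pts
    raise AssertionError(f"no bin for {value}")  # pragma: no cover


# APACHE II acute-physiology bins (closed intervals at printed precision)
APACHE2_BINS: dict[str, dict] = {
    "temperature": {
        "precision": 1,
        "bins": [
            (None, 29.9, 4), (30.0, 31.9, 3), (32.0, 33.9, 2), (34.0, 35.9, 1),
            (36.0, 38.4, 0), (38.5, 38.9, 1), (39.0, 40.9, 3), (41.0, None, 4),
        ],
    },
    "map_pressure": {
        "precision": 0,
        "bins": [
            (None, 49, 4), (50, 69, 2), (70, 109, 0), (110, 129, 2),
            (130, 159, 3), (160, None, 4),
        ],
    },
    "heart_rate": {
        "precision": 0,
        "bins": [
            (None, 39, 4), (40, 54, 3), (55, 69, 2), (70, 109, 0),
            (110, 139, 2), (140, 179, 3), (180, None, 4),
        ],
    },
    "resp_rate": {
        "precision": 0,
        "bins": [
            (None, 5, 4), (6, 9, 2), (10, 11, 1), (12, 24, 0),
            (25, 34, 1), (35, 49, 3), (50, None, 4),
        ],
    },
    "aado2": {  # used when FiO2 >= 0.5
        "precision": 0,
        "bins": [(None, 199, 0), (200, 349, 2), (350, 499, 3), (500, None, 4)],
    },
    "pao2": {  # used when FiO2 < 0.5
        "precision": 0,
        "bins": [(None, 54, 4), (55, 60, 3), (61, 70, 1), (71, None, 0)],
    },
    "arterial_ph": {
        "precision": 2,
        "bins": [
            (None, 7.14, 4), (7.15, 7.24, 3), (7.25, 7.32, 2), (7.33, 7.49, 0),
            (7.50, 7.59, 1), (7.60, 7.69, 3), (7.70, None, 4),
        ],
    },
    "hco3": {  # fallback when no arterial blood gas
        "precision": 1,
        "bins": [
            (None, 14.9, 4), (15.0, 17.9, 3), (18.0, 21.9, 2), (22.0, 31.9, 0),
            (32.0, 40.9, 1), (41.0, 51.9, 3), (52.0, None, 4),
        ],
    },
    "sodium": {
        "precision": 0,
        "bins": [
            (None, 110, 4), (111, 119, 3), (120, 129, 2), (130, 149, 0),
            (150, 154, 1), (155, 159, 2), (160, 179, 3), (180, None, 4),
        ],
    },
    "potassium": {
        "precision": 1,
        "bins": [
            (None, 2.4, 4), (2.5, 2.9, 2), (3.0, 3.4, 1), (3.5, 5.4, 0),
            (5.5, 5.9, 1), (6.0, 6.9, 3), (7.0, None, 4),
        ],
    },
    "creatinine_mgdl": {  # doubled if acute renal failure
        "precision": 1,
        "bins": [(None, 0.5, 2), (0.6, 1.4, 0), (1.5, 1.9, 2), (2.0, 3.4, 3), (3.5, None, 4)],
    },
    "hematocrit": {
        "precision": 1,
        "bins": [
            (None, 19.9, 4), (20.0, 29.9, 2), (30.0, 45.9, 0), (46.0, 49.9, 1),
            (50.0, 59.9, 2), (60.0, None, 4),
        ],
    },
    "wbc": {
        "precision": 1,
        "bins": [(None, 0.9, 4), (1.0, 2.9, 2), (3.0, 14.9, 0), (15.0, 19.9, 1), (20.0, 39.9, 2), (40.0, None, 4)],
    },
    "age": {
        "precision": 0,
        "bins": [(None, 44, 0), (45, 54, 2), (55, 64, 3), (65, 74, 5), (75, None, 6)],
    },
}

# SAPS II bins, half-open [lo, hi): no rounding needed
SAPS2_BINS: dict[str, list] = {
    "age": [(None, 40, 0), (40, 60, 7), (60, 70, 12), (70, 75, 15), (75, 80, 16), (80, None, 18)],
    "heart_rate": [(None, 40, 11), (40, 70, 2), (70, 120, 0), (120, 160, 4), (160, None, 7)],
    "sbp": [(None, 70, 13), (70, 100, 5), (100, 200, 0), (200, None, 2)],
    "temperature": [(None, 39.0, 0), (39.0, None, 3)],
    "pao2_fio2": [(None, 100, 11), (100, 200, 9), (200, None, 6)],  # ventilated only
    "urine_output_l": [(None, 0.500, 11), (0.500, 1.000, 4), (1.000, None, 0)],
    "bun_mgdl": [(None, 28, 0), (28, 84, 6), (84, None, 10)],
    "wbc": [(None, 1.0, 12), (1.0, 20.0, 0), (20.0, None, 3)],
    "potassium": [(None, 3.0, 3), (3.0, 5.0, 0), (5.0, None, 3)],
    "sodium": [(None, 125, 5), (125, 145, 0), (145, None, 1)],
    "hco3": [(None, 15, 6), (15, 20, 3), (20, None, 0)],
    "bilirubin_umol": [(None, 68.4, 0), (68.4, 102.6, 4), (102.6, None, 9)],
    "gcs": [(None, 6, 26), (6, 9, 13), (9, 11, 7), (11, 14, 5), (14, None, 0)],
}

SAPS2_CHRONIC_POINTS = {
    SapsChronic.NONE: 0,
    SapsChronic.METASTATIC_CANCER: 9,
    SapsChronic.HEMATOLOGIC_MALIGNANCY: 10,
    SapsChronic.AIDS: 17,
}

SAPS2_ADMISSION_POINTS = {
    AdmissionType.SCHEDULED_SURGICAL: 0,
    AdmissionType.MEDICAL: 6,
    AdmissionType.UNSCHEDULED_SURGICAL: 8,
}


def _halfopen(value: float, bins) -> int:
    for lo, hi, pts in bins:
        if (lo is None or value >= lo) and (hi is None or value < hi):
            return pts
    raise AssertionError(f"no bin for {value}")  # pragma: no cover


# --------------------------------------------------------------------------
# variable groups


@dataclass(frozen=True)
class VariableGroup:
    """One worst-value abstraction unit of a score.

    ``evaluate`` maps a reading's values (a mapping of field name to
    value, possibly partial) to ``(points, assignments)`` or ``None``
    when the reading cannot assess this variable. ``assignments`` are
    the snapshot fields the winning reading contributes.
    """

    name: str
    fields: tuple[str, ...]
    evaluate: Callable[[Mapping], Optional[tuple[int, dict]]]


def _simple(name: str, field: str, points_fn) -> VariableGroup:
    def ev(values: Mapping):
        v = values.get(field)
        if v is None:
            return None
        return points_fn(v), {field: v}

    return VariableGroup(name=name, fields=(field,), evaluate=ev)


def _apache_oxygenation(values: Mapping):
    fio2 = values.get("fio2")
    pao2 = values.get("pao2")
    aado2 = values.get("aado2")
    paco2 = values.get("paco2")
    if fio2 is not None and fio2 >= 0.5:
        if aado2 is None and pao2 is not None and paco2 is not None:
            aado2 = fio2 * 713.0 - paco2 / 0.8 - pao2
        if aado2 is None:
            return None
        pts = _binned(aado2, **APACHE2_BINS["aado2"])
        return pts, {k: values.get(k) for k in ("fio2", "pao2", "paco2", "aado2") if values.get(k) is not None}
    if pao2 is None:
        return None
    pts = _binned(pao2, **APACHE2_BINS["pao2"])
    out = {"pao2": pao2}
    if fio2 is not None:
        out["fio2"] = fio2
    return pts, out


def _apache_acid_base(values: Mapping):
    ph = values.get("arterial_ph")
    if ph is not None:
        return _binned(ph, **APACHE2_BINS["arterial_ph"]), {"arterial_ph": ph}
    hco3 = values.get("hco3")
    if hco3 is not None:
        return _binned(hco3, **APACHE2_BINS["hco3"]), {"hco3": hco3}
    return None


def _apache_creatinine(values: Mapping):
    cr = values.get("creatinine")
    if cr is None:
        return None
    mgdl = cr / MMOL_CREATININE_PER_MGDL
    pts = _binned(mgdl, **APACHE2_BINS["creatinine_mgdl"])
    arf = bool(values.get("acute_renal_failure", False))
    if arf:
        pts *= 2
    out = {"creatinine": cr}
    if values.get("acute_renal_failure") is not None:
        out["acute_renal_failure"] = values["acute_renal_failure"]
    return pts, out


def _apache_gcs(values: Mapping):
    e, v, m = values.get("gcs_eye"), values.get("gcs_verbal"), values.get("gcs_motor")
    if e is None or v is None or m is None:
        return None
    return 15 - score_gcs(e, v, m), {"gcs_eye": e, "gcs_verbal": v, "gcs_motor": m}


def _apache_chronic(values: Mapping):
    severe = values.get("severe_chronic_condition")
    if severe is None:
        return None
    if not severe:
        return 0, {"severe_chronic_condition": False}
    adm = values.get("admission_type")
    if adm is None:
        return None
    pts = 2 if adm is AdmissionType.SCHEDULED_SURGICAL else 5
    return pts, {"severe_chronic_condition": True, "admission_type": adm}


APACHE2_GROUPS: tuple[VariableGroup, ...] = (
    _simple("temperature", "temperature_ax", lambda v: _binned(v, **APACHE2_BINS["temperature"])),
    _simple("map_pressure", "map_pressure", lambda v: _binned(v, **APACHE2_BINS["map_pressure"])),
    _simple("heart_rate", "heart_rate", lambda v: _binned(v, **APACHE2_BINS["heart_rate"])),
    _simple("resp_rate", "resp_rate", lambda v: _binned(v, **APACHE2_BINS["resp_rate"])),
    VariableGroup("oxygenation", ("fio2", "pao2", "paco2", "aado2"), _apache_oxygenation),
    VariableGroup("acid_base", ("arterial_ph", "hco3"), _apache_acid_base),
    _simple("sodium", "sodium", lambda v: _binned(v, **APACHE2_BINS["sodium"])),
    _simple("potassium", "potassium", lambda v: _binned(v, **APACHE2_BINS["potassium"])),
    VariableGroup("creatinine", ("creatinine", "acute_renal_failure"), _apache_creatinine),
    _simple("hematocrit", "hematocrit", lambda v: _binned(v, **APACHE2_BINS["hematocrit"])),
    _simple("wbc", "wbc", lambda v: _binned(v, **APACHE2_BINS["wbc"])),
    VariableGroup("gcs", ("gcs_eye", "gcs_verbal", "gcs_motor"), _apache_gcs),
    _simple("age", "age", lambda v: _binned(v, **APACHE2_BINS["age"])),
    VariableGroup("chronic_health", ("severe_chronic_condition", "admission_type"), _apache_chronic),
)


def _saps_oxygenation(values: Mapping):
    intubated = values.get("intubated")
    if intubated is None:
        return None
    if not intubated:
        return 0, {"intubated": False}
    pao2, fio2 = values.get("pao2"), values.get("fio2")
    if pao2 is None or fio2 is None or fio2 <= 0:
        return None
    pts = _halfopen(pao2 / fio2, SAPS2_BINS["pao2_fio2"])
    return pts, {"intubated": True, "pao2": pao2, "fio2": fio2}


def _saps_gcs(values: Mapping):
    e, v, m = values.get("gcs_eye"), values.get("gcs_verbal"), values.get("gcs_motor")
    if e is None or v is None or m is None:
        return None
    return (
        _halfopen(score_gcs(e, v, m), SAPS2_BINS["gcs"]),
        {"gcs_eye": e, "gcs_verbal": v, "gcs_motor": m},
    )


SAPS2_GROUPS: tuple[VariableGroup, ...] = (
    _simple("age", "age", lambda v: _halfopen(v, SAPS2_BINS["age"])),
    _simple("heart_rate", "heart_rate", lambda v: _halfopen(v, SAPS2_BINS["heart_rate"])),
    _simple("sbp", "sbp", lambda v: _halfopen(v, SAPS2_BINS["sbp"])),
    _simple("temperature", "temperature_ax", lambda v: _halfopen(v, SAPS2_BINS["temperature"])),
    VariableGroup("oxygenation", ("intubated", "pao2", "fio2"), _saps_oxygenation),
    _simple(
        "urine_output",
        "urine_output_24h",
        lambda v: _halfopen(v / 1000.0, SAPS2_BINS["urine_output_l"]),
    ),
    _simple("bun", "bun", lambda v: _halfopen(v, SAPS2_BINS["bun_mgdl"])),
    _simple("wbc", "wbc", lambda v: _halfopen(v, SAPS2_BINS["wbc"])),
    _simple("potassium", "potassium", lambda v: _halfopen(v, SAPS2_BINS["potassium"])),
    _simple("sodium", "sodium", lambda v: _halfopen(v, SAPS2_BINS["sodium"])),
    _simple("hco3", "hco3", lambda v: _halfopen(v, SAPS2_BINS["hco3"])),
    _simple("bilirubin", "bilirubin", lambda v: _halfopen(v, SAPS2_BINS["bilirubin_umol"])),
    VariableGroup("gcs", ("gcs_eye", "gcs_verbal", "gcs_motor"), _saps_gcs),
    _simple("chronic_disease", "saps_chronic", lambda v: SAPS2_CHRONIC_POINTS[v]),
    _simple("admission_type", "admission_type", lambda v: SAPS2_ADMISSION_POINTS[v]),
)


def _gcs_component(name: str, field: str, worst: int, best: int) -> VariableGroup:
    # derangement = distance below the best achievable component value
    def ev(values: Mapping):
        v = values.get(field)
        if v is None:
            return None
        if not worst <= v <= best:
            raise ValueError(f"{field} must be in [{worst}, {best}], got {v}")
        return best - v, {field: v}

    return VariableGroup(name=name, fields=(field,), evaluate=ev)


GCS_GROUPS: tuple[VariableGroup, ...] = (
    _gcs_component("eye", "gcs_eye", 1, 4),
    _gcs_component("verbal", "gcs_verbal", 1, 5),
    _gcs_component("motor", "gcs_motor", 1, 6),
)

FOUR_GROUPS: tuple[VariableGroup, ...] = (
    _gcs_component("eye", "four_eye", 0, 4),
    _gcs_component("motor", "four_motor", 0, 4),
    _gcs_component("brainstem", "four_brainstem", 0, 4),
    _gcs_component("respiration", "four_respiration", 0, 4),
)


# --------------------------------------------------------------------------
# full-input scorers


def _values_of(inputs: ComparatorInputs) -> dict:
    from dataclasses import fields as dc_fields

    return {f.name: getattr(inputs, f.name) for f in dc_fields(inputs)}


def _score_groups(inputs: ComparatorInputs, groups, assume_normal: bool) -> int:
    values = _values_of(inputs)
    total = 0
    missing = []
    for g in groups:
        res = g.evaluate(values)
        if res is None:
            if assume_normal:
                continue
            missing.append(g.name)
        else:
            total += res[0]
    if missing:
        raise MissingDataError(missing)
    return total


def score_apache2(inputs: ComparatorInputs, assume_normal: bool = False) -> int:
    """APACHE II total: acute physiology + age + chronic health (0-71)."""
    return _score_groups(inputs, APACHE2_GROUPS, assume_normal)


def score_saps2(inputs: ComparatorInputs, assume_normal: bool = False) -> int:
    """SAPS II total over its 17 variables (0-163)."""
    return _score_groups(inputs, SAPS2_GROUPS, assume_normal)
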