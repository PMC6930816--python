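"""INCNS scoresheet: 19 items, 5 categories, 0-44 points.

The score sums 19 bedside/laboratory items grouped into inflammation,
nutrition, consciousness, neurologic function and systemic condition.
Every item is worth 0-3 points; higher is worse. Numeric items are
binned after rounding the raw value to the precision the scoresheet is
printed at, which makes the lookup total and deterministic (the printed
bins have decimal-width gaps, e.g. WBC 10.0 vs 10.1).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

__all__ = [
    "Arousal",
    "Awareness",
    "ReflexResponse",
    "Verbal",
    "MotorMode",
    "MotorPain",
    "Swallow",
    "VentInteraction",
    "Category",
    "Item",
    "ItemScore",
    "INCNSResult",
    "PatientSnapshot",
    "MissingDataError",
    "score_item",
    "score_motor",
    "score_respiration",
    "score_incns",
    "worst_case_snapshot",
    "normal_snapshot",
    "NUMERIC_BINS",
    "CATEGORICAL_POINTS",
    "ITEM_CATEGORY",
    "ITEM_MAX",
]


# --------------------------------------------------------------------------
# enums


class Arousal(str, enum.Enum):
    SPONTANEOUS = "spontaneous"
    TO_VERBAL = "to_verbal"
    TO_PAIN = "to_pain"
    NONE = "none"


class Awareness(str, enum.Enum):
    CORRECT_RESPONSE = "correct_response"
    CONFUSED_RESPONSE = "confused_response"
    NONREFLEX_MOVEMENTS = "nonreflex_movements"
    NONE = "none"


class ReflexResponse(str, enum.Enum):
    """Pupillary-light / corneal reflex examination result."""

    BILATERAL_SENSITIVE = "bilateral_sensitive"
    UNILATERAL_SLOW_ABSENT = "unilateral_slow_absent"
    BILATERAL_SLOW_ABSENT = "bilateral_slow_absent"


class Verbal(str, enum.Enum):
    ACCURATE = "accurate"
    CONFUSED_INAPPROPRIATE = "confused_inappropriate"
    INCOMPREHENSIBLE_NONE = "incomprehensible_none"


class MotorMode(str, enum.Enum):
    STRENGTH_TEST = "strength_test"
    PAIN_RESPONSE = "pain_response"


class MotorPain(str, enum.Enum):
    OBEYS = "obeys"
    LOCALIZES_WITHDRAWS = "localizes_withdraws"
    FLEXES_EXTENDS = "flexes_extends"
    NONE = "none"


class Swallow(str, enum.Enum):
    WST_I_II = "wst_I_II"
    WST_III_IV_OR_UNABLE = "wst_III_IV_or_unable"


class VentInteraction(str, enum.Enum):
    ABOVE_RATE = "above_rate"
    AT_RATE_OR_APNEA = "at_rate_or_apnea"


class Category(str, enum.Enum):
    INFLAMMATION = "inflammation"
    NUTRITION = "nutrition"
    CONSCIOUSNESS = "consciousness"
    NEUROLOGIC_FUNCTION = "neurologic_function"
    SYSTEMIC_CONDITION = "systemic_condition"


class Item(str, enum.Enum):
    WBC = "wbc"
    TEMPERATURE = "temperature_ax"
    ALBUMIN = "albumin"
    AROUSAL = "arousal"
    AWARENESS = "awareness"
    PUPILLARY_REFLEX = "pupillary_reflex"
    CORNEAL_REFLEX = "corneal_reflex"
    VERBAL = "verbal"
    MOTOR = "motor"
    SWALLOW = "swallow"
    RESPIRATION = "respiration"
    AGE = "age"
    HEART_RATE = "heart_rate"
    SBP = "sbp"
    GLUCOSE = "glucose"
    SODIUM = "sodium"
    POTASSIUM = "potassium"
    CREATININE = "creatinine"
    BILIRUBIN = "bilirubin"


# --------------------------------------------------------------------------
# bin tables
#
# Numeric bins are (lo, hi, points) triples on the value rounded to
# ``precision`` decimals; ``None`` means unbounded. Bins are contiguous
# at the stated precision, so lookup is total.

NUMERIC_BINS: dict[Item, dict] = {
    Item.WBC: {
        "precision": 1,
        "bins": [
            (None, 2.8, 2),
            (2.9, 3.9, 1),
            (4.0, 10.0, 0),
            (10.1, 25.0, 1),
            (25.1, None, 2),
        ],
    },
    Item.TEMPERATURE: {
        "precision": 1,
        "bins": [
            (None, 35.9, 1),
            (36.0, 38.4, 0),
            (38.5, 40.0, 1),
            (40.1, None, 2),
        ],
    },
    Item.ALBUMIN: {
        "precision": 1,
        "bins": [
            (None, 24.9, 2),
            (25.0, 34.9, 1),
            (35.0, None, 0),
        ],
    },
    Item.AGE: {
        "precision": 0,
        "bins": [
            (None, 44, 0),
            (45, 64, 1),
            (65, 74, 2),
            (75, None, 3),
        ],
    },
    Item.HEART_RATE: {
        "precision": 0,
        "bins": [
            (None, 39, 2),
            (40, 59, 1),
            (60, 100, 0),
            (101, 149, 1),
            (150, None, 2),
        ],
    },
    Item.SBP: {
        "precision": 0,
        "bins": [
            (None, 69, 2),
            (70, 89, 1),
            (90, 140, 0),
            (141, 199, 1),
            (200, None, 2),
        ],
    },
    Item.GLUCOSE: {
        "precision": 1,
        "bins": [
            (None, 2.1, 2),
            (2.2, 3.8, 1),
            (3.9, 11.1, 0),
            (11.2, 19.3, 1),
            (19.4, None, 2),
        ],
    },
    Item.SODIUM: {
        "precision": 0,
        "bins": [
            (None, 119, 2),
            (120, 129, 1),
            (130, 150, 0),
            (151, 159, 1),
            (160, None, 2),
        ],
    },
    Item.POTASSIUM: {
        "precision": 1,
        "bins": [
            (None, 2.4, 2),
            (2.5, 3.4, 1),
            (3.5, 5.5, 0),
            (5.6, 6.9, 1),
            (7.0, None, 2),
        ],
    },
    Item.CREATININE: {
        "precision": 0,
        "bins": [
            (None, 43, 1),
            (44, 132, 0),
            (133, 171, 1),
            (172, None, 2),
        ],
    },
    Item.BILIRUBIN: {
        "precision": 1,
        "bins": [
            (None, 34.1, 0),
            (34.2, 102.5, 1),
            (102.6, None, 2),
        ],
    },
}

CATEGORICAL_POINTS: dict[Item, dict] = {
    Item.AROUSAL: {
        Arousal.SPONTANEOUS: 0,
        Arousal.TO_VERBAL: 1,
        Arousal.TO_PAIN: 2,
        Arousal.NONE: 3,
    },
    Item.AWARENESS: {
        Awareness.CORRECT_RESPONSE: 0,
        Awareness.CONFUSED_RESPONSE: 1,
        Awareness.NONREFLEX_MOVEMENTS: 2,
        Awareness.NONE: 3,
    },
    # brainstem reflexes deliberately skip 1 point: slow/absent responses
    # are weighted up
    Item.PUPILLARY_REFLEX: {
        ReflexResponse.BILATERAL_SENSITIVE: 0,
        ReflexResponse.UNILATERAL_SLOW_ABSENT: 2,
        ReflexResponse.BILATERAL_SLOW_ABSENT: 3,
    },
    Item.CORNEAL_REFLEX: {
        ReflexResponse.BILATERAL_SENSITIVE: 0,
        ReflexResponse.UNILATERAL_SLOW_ABSENT: 2,
        ReflexResponse.BILATERAL_SLOW_ABSENT: 3,
    },
    Item.VERBAL: {
        Verbal.ACCURATE: 0,
        Verbal.CONFUSED_INAPPROPRIATE: 1,
        Verbal.INCOMPREHENSIBLE_NONE: 2,
    },
    Item.SWALLOW: {
        Swallow.WST_I_II: 0,
        Swallow.WST_III_IV_OR_UNABLE: 1,
    },
}

MOTOR_PAIN_POINTS = {
    MotorPain.OBEYS: 0,
    MotorPain.LOCALIZES_WITHDRAWS: 1,
    MotorPain.FLEXES_EXTENDS: 2,
    MotorPain.NONE: 3,
}

ITEM_CATEGORY: dict[Item, Category] = {
    Item.WBC: Category.INFLAMMATION,
    Item.TEMPERATURE: Category.INFLAMMATION,
    Item.ALBUMIN: Category.NUTRITION,
    Item.AROUSAL: Category.CONSCIOUSNESS,
    Item.AWARENESS: Category.CONSCIOUSNESS,
    Item.PUPILLARY_REFLEX: Category.NEUROLOGIC_FUNCTION,
    Item.CORNEAL_REFLEX: Category.NEUROLOGIC_FUNCTION,
    Item.VERBAL: Category.NEUROLOGIC_FUNCTION,
    Item.MOTOR: Category.NEUROLOGIC_FUNCTION,
    Item.SWALLOW: Category.NEUROLOGIC_FUNCTION,
    Item.RESPIRATION: Category.NEUROLOGIC_FUNCTION,
    Item.AGE: Category.SYSTEMIC_CONDITION,
    Item.HEART_RATE: Category.SYSTEMIC_CONDITION,
    Item.SBP: Category.SYSTEMIC_CONDITION,
    Item.GLUCOSE: Category.SYSTEMIC_CONDITION,
    Item.SODIUM: Category.SYSTEMIC_CONDITION,
    Item.POTASSIUM: Category.SYSTEMIC_CONDITION,
    Item.CREATININE: Category.SYSTEMIC_CONDITION,
    Item.BILIRUBIN: Category.SYSTEMIC_CONDITION,
}

ITEM_MAX: dict[Item, int] = {
    Item.WBC: 2,
    Item.TEMPERATURE: 2,
    Item.ALBUMIN: 2,
    Item.AROUSAL: 3,
    Item.AWARENESS: 3,
    Item.PUPILLARY_REFLEX: 3,
    Item.CORNEAL_REFLEX: 3,
    Item.VERBAL: 2,
    Item.MOTOR: 3,
    Item.SWALLOW: 1,
    Item.RESPIRATION: 3,
    Item.AGE: 3,
    Item.HEART_RATE: 2,
    Item.SBP: 2,
    Item.GLUCOSE: 2,
    Item.SODIUM: 2,
    Item.POTASSIUM: 2,
    Item.CREATININE: 2,
    Item.BILIRUBIN: 2,
}

CATEGORY_MAX: dict[Category, int] = {
    Category.INFLAMMATION: 4,
    Category.NUTRITION: 2,
    Category.CONSCIOUSNESS: 6,
    Category.NEUROLOGIC_FUNCTION: 15,
    Category.SYSTEMIC_CONDITION: 17,
}

#: snapshot fields whose values must be non-negative reals
_NONNEGATIVE_FIELDS = (
    "wbc",
    "albumin",
    "glucose",
    "sodium",
    "potassium",
    "creatinine",
    "bilirubin",
    "age",
    "heart_rate",
    "sbp",
    "resp_rate",
)


# --------------------------------------------------------------------------
# domain types


class MissingDataError(ValueError):
    """A required snapshot field is absent and imputation was not requested."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing required field(s): {', '.join(self.missing)}")


@dataclass(frozen=True)
class ItemScore:
    item: Item
    points: int
    category: Category
    imputed: bool = False

    def __post_init__(self):
        if not 0 <= self.points <= ITEM_MAX[self.item]:
            raise ValueError(
                f"{self.item.value}: {self.points} points exceeds "
                f"maximum {ITEM_MAX[self.item]}"
            )


@dataclass(frozen=True)
class INCNSResult:
    total: int
    subtotals: dict[Category, int]
    items: tuple[ItemScore, ...]

    @property
    def imputed_items(self) -> tuple[Item, ...]:
        return tuple(s.item for s in self.items if s.imputed)


@dataclass(frozen=True, kw_only=True)
class PatientSnapshot:
    """Raw values for the 19 scored variables of one patient-window.

    Any field may be ``None`` (missing); the missing-data policy is
    applied at scoring time, not construction time. Exactly one motor
    assessment and one respiration description must be populated when
    their mode/intubation flags are set.
    """

    wbc: Optional[float] = None
    temperature_ax: Optional[float] = None
    albumin: Optional[float] = None
    arousal: Optional[Arousal] = None
    awareness: Optional[Awareness] = None
    pupillary_reflex: Optional[ReflexResponse] = None
    corneal_reflex: Optional[ReflexResponse] = None
    #: comparator subclasses relax the intubated/resp_rate exclusivity
    _allow_resp_rate_when_intubated = False

    verbal: Optional[Verbal] = None
    motor_mode: Optional[MotorMode] = None
    motor_strength_worst: Optional[int] = None
    motor_strength_unilateral_low: Optional[bool] = None
    motor_pain: Optional[MotorPain] = None
    swallow: Optional[Swallow] = None
    intubated: Optional[bool] = None
    resp_rate: Optional[int] = None
    vent_interaction: Optional[VentInteraction] = None
    age: Optional[int] = None
    heart_rate: Optional[int] = None
    sbp: Optional[int] = None
    glucose: Optional[float] = None
    sodium: Optional[float] = None
    potassium: Optional[float] = None
    creatinine: Optional[float] = None
    bilirubin: Optional[float] = None

    def __post_init__(self):
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name, None)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")
        v = self.temperature_ax
        if v is not None and not math.isfinite(v):
            raise ValueError(f"temperature_ax must be finite, got {v!r}")
        if self.motor_mode is MotorMode.STRENGTH_TEST:
            if self.motor_pain is not None:
                raise ValueError("motor_pain must be absent under strength_test mode")
            if self.motor_strength_worst is not None and not (
                0 <= self.motor_strength_worst <= 5
            ):
                raise ValueError("motor_strength_worst must be an MRC grade 0-5")
        elif self.motor_mode is MotorMode.PAIN_RESPONSE:
            if self.motor_strength_worst is not None or (
                self.motor_strength_unilateral_low is not None
            ):
                raise ValueError("strength fields must be absent under pain_response mode")
        if (
            not self._allow_resp_rate_when_intubated
            and self.intubated is True
            and self.resp_rate is not None
        ):
            raise ValueError("resp_rate must be absent when intubated")
        if self.intubated is False and self.vent_interaction is not None:
            raise ValueError("vent_interaction must be absent when not intubated")


# --------------------------------------------------------------------------
# scoring


def _round_to(value: float, decimals: int) -> Decimal:
    q = Decimal(1).scaleb(-decimals)
    return Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)


def _lookup_numeric(item: Item, value: float) -> int:
    spec = NUMERIC_BINS[item]
    v = _round_to(value, spec["precision"])
    for lo, hi, pts in spec["bins"]:
        if (lo is None or v >= Decimal(repr(lo))) and (
            hi is None or v <= Decimal(repr(hi))
        ):
            return pts
    raise AssertionError(f"no bin for {item.value}={value}")  # pragma: no cover


def score_item(item: Item, value) -> ItemScore:
    """Score one single-valued item (motor and respiration are composite,
    use :func:`score_motor` / :func:`score_respiration`)."""
    if not isinstance(item, Item):
        raise ValueError(f"unknown item: {item!r}")
    if item in (Item.MOTOR, Item.RESPIRATION):
        raise ValueError(f"{item.value} is composite; use its dedicated scorer")
    if value is None:
        raise MissingDataError([item.value])
    if item in NUMERIC_BINS:
        if value < 0 and item is not Item.TEMPERATURE:
            raise ValueError(f"{item.value} must be non-negative, got {value!r}")
        pts = _lookup_numeric(item, value)
    else:
        table = CATEGORICAL_POINTS[item]
        if value not in table:
            raise ValueError(f"invalid value for {item.value}: {value!r}")
        pts = table[value]
    return ItemScore(item=item, points=pts, category=ITEM_CATEGORY[item])


def score_motor(snapshot: PatientSnapshot) -> ItemScore:
    """Motor item: either the worst-limb MRC strength grade or the motor
    response to pain, whichever assessment was performed."""
    mode = snapshot.motor_mode
    if mode is None:
        raise MissingDataError(["motor_mode"])
    if mode is MotorMode.STRENGTH_TEST:
        grade = snapshot.motor_strength_worst
        if grade is None:
            raise MissingDataError(["motor_strength_worst"])
        if snapshot.motor_pain is not None:
            raise ValueError("both motor assessments populated")
        if grade >= 4:
            pts = 0
        elif grade >= 2:
            pts = 1
        else:  # worst limb at grade <= 1
            unilateral = snapshot.motor_strength_unilateral_low
            if unilateral is None:
                raise MissingDataError(["motor_strength_unilateral_low"])
            pts = 2 if unilateral else 3
    else:
        if snapshot.motor_pain is None:
            raise MissingDataError(["motor_pain"])
        if snapshot.motor_strength_worst is not None:
            raise ValueError("both motor assessments populated")
        pts = MOTOR_PAIN_POINTS[snapshot.motor_pain]
    return ItemScore(item=Item.MOTOR, points=pts, category=Category.NEUROLOGIC_FUNCTION)


def score_respiration(snapshot: PatientSnapshot) -> ItemScore:
    """Respiration item: four degrees spanning spontaneous breathing
    through ventilator dependence."""
    if snapshot.intubated is None:
        raise MissingDataError(["intubated"])
    if snapshot.intubated:
        if snapshot.vent_interaction is None:
            raise MissingDataError(["vent_interaction"])
        pts = 2 if snapshot.vent_interaction is VentInteraction.ABOVE_RATE else 3
    else:
        if snapshot.resp_rate is None:
            raise MissingDataError(["resp_rate"])
        pts = 0 if 12 <= round(snapshot.resp_rate) <= 24 else 1
    return ItemScore(
        item=Item.RESPIRATION, points=pts, category=Category.NEUROLOGIC_FUNCTION
    )


_SIMPLE_FIELD_OF_ITEM = {
    Item.WBC: "wbc",
    Item.TEMPERATURE: "temperature_ax",
    Item.ALBUMIN: "albumin",
    Item.AROUSAL: "arousal",
    Item.AWARENESS: "awareness",
    Item.PUPILLARY_REFLEX: "pupillary_reflex",
    Item.CORNEAL_REFLEX: "corneal_reflex",
    Item.VERBAL: "verbal",
    Item.SWALLOW: "swallow",
    Item.AGE: "age",
    Item.HEART_RATE: "heart_rate",
    Item.SBP: "sbp",
    Item.GLUCOSE: "glucose",
    Item.SODIUM: "sodium",
    Item.POTASSIUM: "potassium",
    Item.CREATININE: "creatinine",
    Item.BILIRUBIN: "bilirubin",
}


def score_incns(snapshot: PatientSnapshot, assume_normal: bool = False) -> INCNSResult:
    """Score a snapshot into 19 item scores, 5 category subtotals and a
    0-44 total.

    Parameters
    ----------
    snapshot
        The raw patient values.
    assume_normal
        If True, missing items are scored 0 points and flagged as imputed
        on the result; if False (default), any missing required field
        raises :class:`MissingDataError` naming every absent field.

    Notes
    -----
    Intubated patients are always scored "incomprehensible speech/none"
    (2 points) on the verbal item; a supplied verbal value is overridden
    with a warning.
    """
    missing: list[str] = []
    scores: list[ItemScore] = []

    def _imputed(item: Item) -> ItemScore:
        return ItemScore(item=item, points=0, category=ITEM_CATEGORY[item], imputed=True)

    for item in Item:
        if item is Item.MOTOR:
            try:
                scores.append(score_motor(snapshot))
            except MissingDataError as e:
                if assume_normal:
                    scores.append(_imputed(item))
                else:
                    missing.extend(e.missing)
            continue
        if item is Item.RESPIRATION:
            try:
                scores.append(score_respiration(snapshot))
            except MissingDataError as e:
                if assume_normal:
                    scores.append(_imputed(item))
                else:
                    missing.extend(e.missing)
            continue

        field_name = _SIMPLE_FIELD_OF_ITEM[item]
        value = getattr(snapshot, field_name)

        if item is Item.VERBAL and snapshot.intubated:
            if value is not None and value is not Verbal.INCOMPREHENSIBLE_NONE:
                warnings.warn(
                    "intubated patient: verbal item overridden to "
                    "incomprehensible/none",
                    stacklevel=2,
                )
            value = Verbal.INCOMPREHENSIBLE_NONE

        if value is None:
            if assume_normal:
                scores.append(_imputed(item))
            else:
                missing.append(field_name)
            continue
        scores.append(score_item(item, value))

    if missing:
        raise MissingDataError(missing)

    subtotals = {c: 0 for c in Category}
    for s in scores:
        subtotals[s.category] += s.points
    return INCNSResult(
        total=sum(subtotals.values()), subtotals=subtotals, items=tuple(scores)
    )


# --------------------------------------------------------------------------
# reference snapshots


def normal_snapshot(**overrides) -> PatientSnapshot:
    """A snapshot with every variable in a 0-point bin."""
    base = dict(
        wbc=7.0,
        temperature_ax=36.8,
        albumin=40.0,
        arousal=Arousal.SPONTANEOUS,
        awareness=Awareness.CORRECT_RESPONSE,
        pupillary_reflex=ReflexResponse.BILATERAL_SENSITIVE,
        corneal_reflex=ReflexResponse.BILATERAL_SENSITIVE,
        verbal=Verbal.ACCURATE,
        motor_mode=MotorMode.STRENGTH_TEST,
        motor_strength_worst=5,
        motor_strength_unilateral_low=False,
        swallow=Swallow.WST_I_II,
        intubated=False,
        resp_rate=16,
        age=30,
        heart_rate=75,
        sbp=120,
        glucose=5.5,
        sodium=140.0,
        potassium=4.0,
        creatinine=80.0,
        bilirubin=10.0,
    )
    base.update(overrides)
    return PatientSnapshot(**base)


def worst_case_snapshot() -> PatientSnapshot:
    """A snapshot with every variable in its maximum-point bin, built
    from the bin tables themselves (a representative value is drawn from
    each item's worst bin)."""

    def worst_numeric(item: Item) -> float:
        spec = NUMERIC_BINS[item]
        lo, hi, _ = max(spec["bins"], key=lambda b: b[2])
        if lo is not None:
            return float(lo)
        return float(hi)

    return PatientSnapshot(
        wbc=worst_numeric(Item.WBC),
        temperature_ax=worst_numeric(Item.TEMPERATURE),
        albumin=worst_numeric(Item.ALBUMIN),
        arousal=max(CATEGORICAL_POINTS[Item.AROUSAL], key=CATEGORICAL_POINTS[Item.AROUSAL].get),
        awareness=max(CATEGORICAL_POINTS[Item.AWARENESS], key=CATEGORICAL_POINTS[Item.AWARENESS].get),
        pupillary_reflex=max(
            CATEGORICAL_POINTS[Item.PUPILLARY_REFLEX],
            key=CATEGORICAL_POINTS[Item.PUPILLARY_REFLEX].get,
        ),
        corneal_reflex=max(
            CATEGORICAL_POINTS[Item.CORNEAL_REFLEX],
            key=CATEGORICAL_POINTS[Item.CORNEAL_REFLEX].get,
        ),
        verbal=max(CATEGORICAL_POINTS[Item.VERBAL], key=CATEGORICAL_POINTS[Item.VERBAL].get),
        motor_mode=MotorMode.PAIN_RESPONSE,
        motor_pain=max(MOTOR_PAIN_POINTS, key=MOTOR_PAIN_POINTS.get),
        swallow=max(CATEGORICAL_POINTS[Item.SWALLOW], key=CATEGORICAL_POINTS[Item.SWALLOW].get),
        intubated=True,
        vent_interaction=VentInteraction.AT_RATE_OR_APNEA,
        age=int(worst_numeric(Item.AGE)),
        heart_rate=int(worst_numeric(Item.HEART_RATE)),
        sbp=int(worst_numeric(Item.SBP)),
        glucose=worst_numeric(Item.GLUCOSE),
        sodium=worst_numeric(Item.SODIUM),
        potassium=worst_numeric(Item.POTASSIUM),
        creatinine=worst_numeric(Item.CREATININE),
        bilirubin=worst_numeric(Item.BILIRUBIN),
    )
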