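import json
import warnings
from importlib import resources as importlib_resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import incns.scoresheet as sh
from incns.scoresheet import (
    CATEGORICAL_POINTS,
    CATEGORY_MAX,
    ITEM_CATEGORY,
    ITEM_MAX,
    NUMERIC_BINS,
    Arousal,
    Awareness,
    Category,
    Item,
    MissingDataError,
    MotorMode,
    MotorPain,
    PatientSnapshot,
    ReflexResponse,
    Swallow,
    VentInteraction,
    Verbal,
    normal_snapshot,
    score_incns,
    score_item,
    score_motor,
    score_respiration,
    worst_case_snapshot,
)

# ---------------------------------------------------------------------------
# independent per-item oracle for the worked 26-point example: a literal
# transcription of the printed scoresheet, kept separate from the scorer

EXAMPLE_ORACLE = {
    "age_70": 2,            # 65 ~ 74
    "wbc_12.0": 1,          # 10.1 ~ 25.0
    "temp_39.0": 1,         # 38.5 ~ 40
    "albumin_30": 1,        # 25 ~ 34.9
    "arousal_to_pain": 2,
    "awareness_nonreflex": 2,
    "pupil_unilateral": 2,
    "corneal_bilateral_sensitive": 0,
    "verbal_incomprehensible": 2,
    "motor_pain_flexes": 2,
    "swallow_unable": 1,
    "resp_intubated_above_rate": 2,
    "hr_110": 1,            # 101 ~ 149
    "sbp_150": 1,           # 141 ~ 199
    "glucose_12.0": 1,      # 11.2 ~ 19.3
    "sodium_155": 1,        # 151 ~ 159
    "potassium_3.0": 1,     # 2.5 ~ 3.4
    "creatinine_180": 2,    # >= 172
    "bilirubin_40": 1,      # 34.2 ~ 102.5
}


class TestScoreIncnsExamples:
    def test_all_normal_scores_zero(self, all_normal):
        result = score_incns(all_normal)
        assert result.total == 0
        assert all(s.points == 0 for s in result.items)

    def test_worst_case_scores_44(self, all_worst):
        result = score_incns(all_worst)
        assert result.total == 44

    def test_worked_example_totals_26(self, example_snapshot):
        assert sum(EXAMPLE_ORACLE.values()) == 26
        result = score_incns(example_snapshot)
        assert result.total == 26

    def test_pure_function(self, example_snapshot):
        r1 = score_incns(example_snapshot)
        r2 = score_incns(example_snapshot)
        assert r1 == r2


class TestItemBins:
    @pytest.mark.parametrize(
        "item,value,expected",
        [
            (Item.WBC, 10.0, 0),
            (Item.WBC, 10.1, 1),
            (Item.WBC, 25.0, 1),
            (Item.WBC, 25.1, 2),
            (Item.WBC, 4.0, 0),
            (Item.WBC, 3.9, 1),
            (Item.WBC, 2.9, 1),
            (Item.WBC, 2.8, 2),
            (Item.TEMPERATURE, 36.0, 0),
            (Item.TEMPERATURE, 35.9, 1),
            (Item.TEMPERATURE, 38.4, 0),
            (Item.TEMPERATURE, 38.5, 1),
            (Item.TEMPERATURE, 40.0, 1),
            (Item.TEMPERATURE, 40.1, 2),
            (Item.ALBUMIN, 35.0, 0),
            (Item.ALBUMIN, 34.9, 1),
            (Item.ALBUMIN, 25.0, 1),
            (Item.ALBUMIN, 24.9, 2),
            (Item.AGE, 44, 0),
            (Item.AGE, 45, 1),
            (Item.AGE, 64, 1),
            (Item.AGE, 65, 2),
            (Item.AGE, 74, 2),
            (Item.AGE, 75, 3),
            (Item.HEART_RATE, 60, 0),
            (Item.HEART_RATE, 59, 1),
            (Item.HEART_RATE, 40, 1),
            (Item.HEART_RATE, 39, 2),
            (Item.HEART_RATE, 100, 0),
            (Item.HEART_RATE, 101, 1),
            (Item.HEART_RATE, 149, 1),
            (Item.HEART_RATE, 150, 2),
            (Item.SBP, 90, 0),
            (Item.SBP, 89, 1),
            (Item.SBP, 70, 1),
            (Item.SBP, 69, 2),
            (Item.SBP, 140, 0),
            (Item.SBP, 141, 1),
            (Item.SBP, 199, 1),
            (Item.SBP, 200, 2),
            (Item.GLUCOSE, 3.9, 0),
            (Item.GLUCOSE, 3.8, 1),
            (Item.GLUCOSE, 2.2, 1),
            (Item.GLUCOSE, 2.1, 2),
            (Item.GLUCOSE, 11.1, 0),
            (Item.GLUCOSE, 11.2, 1),
            (Item.GLUCOSE, 19.3, 1),
            (Item.GLUCOSE, 19.4, 2),
            (Item.SODIUM, 130, 0),
            (Item.SODIUM, 129, 1),
            (Item.SODIUM, 120, 1),
            (Item.SODIUM, 119, 2),
            (Item.SODIUM, 150, 0),
            (Item.SODIUM, 151, 1),
            (Item.SODIUM, 159, 1),
            (Item.SODIUM, 160, 2),
            (Item.POTASSIUM, 3.5, 0),
            (Item.POTASSIUM, 3.4, 1),
            (Item.POTASSIUM, 2.5, 1),
            (Item.POTASSIUM, 2.4, 2),
            (Item.POTASSIUM, 5.5, 0),
            (Item.POTASSIUM, 5.6, 1),
            (Item.POTASSIUM, 6.9, 1),
            (Item.POTASSIUM, 7.0, 2),
            (Item.CREATININE, 44, 0),
            (Item.CREATININE, 43, 1),
            (Item.CREATININE, 40, 1),
            (Item.CREATININE, 132, 0),
            (Item.CREATININE, 133, 1),
            (Item.CREATININE, 171, 1),
            (Item.CREATININE, 172, 2),
            (Item.BILIRUBIN, 34.1, 0),
            (Item.BILIRUBIN, 34.2, 1),
            (Item.BILIRUBIN, 102.5, 1),
            (Item.BILIRUBIN, 102.6, 2),
        ],
    )
    def test_printed_boundaries(self, item, value, expected):
        assert score_item(item, value).points == expected

    def test_rounding_to_table_precision(self):
        # one-decimal items round half-up before the bin lookup
        assert score_item(Item.TEMPERATURE, 38.44).points == 0
        assert score_item(Item.TEMPERATURE, 38.45).points == 1
        assert score_item(Item.WBC, 10.04).points == 0
        assert score_item(Item.WBC, 10.05).points == 1
        assert score_item(Item.SODIUM, 150.4).points == 0
        assert score_item(Item.SODIUM, 150.5).points == 1

    def test_categorical_items(self):
        assert score_item(Item.PUPILLARY_REFLEX, ReflexResponse.BILATERAL_SLOW_ABSENT).points == 3
        assert score_item(Item.PUPILLARY_REFLEX, ReflexResponse.UNILATERAL_SLOW_ABSENT).points == 2
        assert score_item(Item.CORNEAL_REFLEX, ReflexResponse.BILATERAL_SENSITIVE).points == 0
        assert score_item(Item.SWALLOW, Swallow.WST_III_IV_OR_UNABLE).points == 1
        assert score_item(Item.AROUSAL, Arousal.NONE).points == 3
        assert score_item(Item.VERBAL, Verbal.CONFUSED_INAPPROPRIATE).points == 1

    def test_reflex_items_never_one_point(self):
        for item in (Item.PUPILLARY_REFLEX, Item.CORNEAL_REFLEX):
            assert 1 not in CATEGORICAL_POINTS[item].values()
            assert sorted(CATEGORICAL_POINTS[item].values()) == [0, 2, 3]

    def test_unknown_item_rejected(self):
        with pytest.raises(ValueError, match="unknown item"):
            score_item("not_an_item", 1.0)

    def test_composite_items_rejected(self):
        with pytest.raises(ValueError, match="composite"):
            score_item(Item.MOTOR, 3)

    def test_negative_lab_rejected(self):
        with pytest.raises(ValueError):
            score_item(Item.WBC, -1.0)

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError, match="invalid value"):
            score_item(Item.AROUSAL, "asleep")

    def test_bin_completeness_exhaustive_sweep(self):
        # every representable value at table precision maps to exactly one bin
        for item, spec in NUMERIC_BINS.items():
            step = 10 ** -spec["precision"]
            finite = [b for e in spec["bins"] for b in e[:2] if b is not None]
            grid = np.arange(0.0, max(finite) + 10 * step, step)
            if item is Item.TEMPERATURE:
                grid = grid[grid >= 25.0]
            for v in np.round(grid, spec["precision"]):
                pts = score_item(item, float(v)).points
                assert 0 <= pts <= ITEM_MAX[item], (item, v, pts)


class TestMonotoneDeterioration:
    """Moving away from the 0-point bin (same direction) never lowers points."""

    @pytest.mark.parametrize("item", sorted(NUMERIC_BINS, key=lambda i: i.value))
    def test_monotone_each_direction(self, item):
        spec = NUMERIC_BINS[item]
        step = 10 ** -spec["precision"]
        zero_bins = [b for b in spec["bins"] if b[2] == 0]
        lo = min(b[0] for b in zero_bins if b[0] is not None) if any(
            b[0] is not None for b in zero_bins
        ) else None
        hi = max(b[1] for b in zero_bins if b[1] is not None) if any(
            b[1] is not None for b in zero_bins
        ) else None
        finite = [b for e in spec["bins"] for b in e[:2] if b is not None]
        top = max(finite) + 20 * step
        if hi is not None:
            values = np.round(np.arange(hi, top, step), spec["precision"])
            pts = [score_item(item, float(v)).points for v in values]
            assert all(b >= a for a, b in zip(pts, pts[1:])), f"{item} increasing side"
        if lo is not None:
            bottom = 25.0 if item is Item.TEMPERATURE else 0.0
            values = np.round(np.arange(lo, bottom - step / 2, -step), spec["precision"])
            values = values[values >= bottom]
            pts = [score_item(item, float(v)).points for v in values]
            assert all(b >= a for a, b in zip(pts, pts[1:])), f"{item} decreasing side"


class TestMotor:
    @pytest.mark.parametrize(
        "grade,unilateral,expected",
        [(5, False, 0), (4, False, 0), (3, False, 1), (2, False, 1), (1, True, 2), (0, True, 2), (1, False, 3), (0, False, 3)],
    )
    def test_strength_path(self, grade, unilateral, expected):
        snap = PatientSnapshot(
            motor_mode=MotorMode.STRENGTH_TEST,
            motor_strength_worst=grade,
            motor_strength_unilateral_low=unilateral,
        )
        assert score_motor(snap).points == expected

    @pytest.mark.parametrize(
        "response,expected",
        [
            (MotorPain.OBEYS, 0),
            (MotorPain.LOCALIZES_WITHDRAWS, 1),
            (MotorPain.FLEXES_EXTENDS, 2),
            (MotorPain.NONE, 3),
        ],
    )
    def test_pain_path(self, response, expected):
        snap = PatientSnapshot(motor_mode=MotorMode.PAIN_RESPONSE, motor_pain=response)
        assert score_motor(snap).points == expected

    def test_both_assessments_rejected_at_construction(self):
        with pytest.raises(ValueError):
            PatientSnapshot(
                motor_mode=MotorMode.STRENGTH_TEST,
                motor_strength_worst=3,
                motor_pain=MotorPain.OBEYS,
            )

    def test_missing_assessment_rejected(self):
        snap = PatientSnapshot(motor_mode=MotorMode.PAIN_RESPONSE)
        with pytest.raises(MissingDataError):
            score_motor(snap)


class TestRespiration:
    @pytest.mark.parametrize("rate,expected", [(12, 0), (18, 0), (24, 0), (11, 1), (25, 1), (5, 1), (40, 1)])
    def test_not_intubated(self, rate, expected):
        snap = PatientSnapshot(intubated=False, resp_rate=rate)
        assert score_respiration(snap).points == expected

    def test_intubated(self):
        above = PatientSnapshot(intubated=True, vent_interaction=VentInteraction.ABOVE_RATE)
        at = PatientSnapshot(intubated=True, vent_interaction=VentInteraction.AT_RATE_OR_APNEA)
        assert score_respiration(above).points == 2
        assert score_respiration(at).points == 3

    def test_intubated_without_interaction_rejected(self):
        snap = PatientSnapshot(intubated=True)
        with pytest.raises(MissingDataError, match="vent_interaction"):
            score_respiration(snap)


class TestInvariants:
    def test_total_conservation(self, example_snapshot, all_normal, all_worst):
        for snap in (example_snapshot, all_normal, all_worst):
            r = score_incns(snap)
            assert r.total == sum(r.subtotals.values()) == sum(s.points for s in r.items)

    def test_category_maxima(self, all_worst):
        r = score_incns(all_worst)
        assert r.subtotals == {
            Category.INFLAMMATION: 4,
            Category.NUTRITION: 2,
            Category.CONSCIOUSNESS: 6,
            Category.NEUROLOGIC_FUNCTION: 15,
            Category.SYSTEMIC_CONDITION: 17,
        }
        assert r.subtotals == CATEGORY_MAX

    def test_nineteen_items_five_categories(self, all_normal):
        r = score_incns(all_normal)
        assert len(r.items) == 19
        assert {s.category for s in r.items} == set(Category)

    def test_item_maxima_match_table(self):
        for item, spec in NUMERIC_BINS.items():
            assert max(b[2] for b in spec["bins"]) == ITEM_MAX[item]
        for item, table in CATEGORICAL_POINTS.items():
            assert max(table.values()) == ITEM_MAX[item]

    @given(
        wbc=st.floats(0, 40),
        temp=st.floats(30, 43),
        glucose=st.floats(0, 35),
        hr=st.integers(0, 250),
    )
    @settings(max_examples=60, deadline=None)
    def test_random_snapshots_conserve_total(self, wbc, temp, glucose, hr):
        snap = normal_snapshot(wbc=wbc, temperature_ax=temp, glucose=glucose, heart_rate=hr)
        r = score_incns(snap)
        assert r.total == sum(s.points for s in r.items)
        assert 0 <= r.total <= 44


class TestMissingDataPolicy:
    def test_missing_fields_listed(self):
        snap = PatientSnapshot(wbc=7.0, age=30)
        with pytest.raises(MissingDataError) as exc:
            score_incns(snap)
        assert "albumin" in exc.value.missing
        assert "arousal" in exc.value.missing
        assert "wbc" not in exc.value.missing

    def test_assume_normal_imputes_and_flags(self):
        snap = PatientSnapshot(wbc=30.0, age=80)
        r = score_incns(snap, assume_normal=True)
        assert r.total == 2 + 3  # wbc worst bin + age worst bin
        assert Item.ALBUMIN in r.imputed_items
        assert Item.WBC not in r.imputed_items
        assert len(r.imputed_items) == 17

    def test_intubated_verbal_override_warns(self):
        snap = normal_snapshot(
            verbal=Verbal.ACCURATE,
            intubated=True,
            resp_rate=None,
            vent_interaction=VentInteraction.ABOVE_RATE,
        )
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            r = score_incns(snap)
        assert any("verbal" in str(x.message) for x in w)
        verbal_item = next(s for s in r.items if s.item is Item.VERBAL)
        assert verbal_item.points == 2


class TestDeclarativeResource:
    """The bundled JSON transcription and the code tables must agree."""

    @pytest.fixture
    def resource(self):
        ref = importlib_resources.files("incns") / "resources" / "incns_bins.json"
        return json.loads(ref.read_text())

    def test_numeric_bins_match(self, resource):
        code = {
            item.value: {
                "precision": spec["precision"],
                "bins": [[b[0], b[1], b[2]] for b in spec["bins"]],
            }
            for item, spec in NUMERIC_BINS.items()
        }
        assert code == resource["numeric_items"]

    def test_categorical_points_match(self, resource):
        code = {
            item.value: {k.value: v for k, v in table.items()}
            for item, table in CATEGORICAL_POINTS.items()
        }
        code["motor_pain"] = {k.value: v for k, v in sh.MOTOR_PAIN_POINTS.items()}
        assert code == resource["categorical_items"]

    def test_categories_match(self, resource):
        code: dict = {}
        for item, cat in ITEM_CATEGORY.items():
            code.setdefault(cat.value, []).append(item.value)
        assert {k: sorted(v) for k, v in code.items()} == {
            k: sorted(v) for k, v in resource["categories"].items()
        }
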