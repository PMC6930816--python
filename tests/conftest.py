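import numpy as np
import pytest

from incns.scoresheet import (
    Arousal,
    Awareness,
    MotorMode,
    MotorPain,
    PatientSnapshot,
    ReflexResponse,
    Swallow,
    VentInteraction,
    Verbal,
    normal_snapshot,
    worst_case_snapshot,
)


@pytest.fixture
def all_normal():
    return normal_snapshot()


@pytest.fixture
def all_worst():
    return worst_case_snapshot()


@pytest.fixture
def example_snapshot():
    """Mixed-severity snapshot used by the 26-point worked example."""
    return PatientSnapshot(
        age=70,
        wbc=12.0,
        temperature_ax=39.0,
        albumin=30.0,
        arousal=Arousal.TO_PAIN,
        awareness=Awareness.NONREFLEX_MOVEMENTS,
        pupillary_reflex=ReflexResponse.UNILATERAL_SLOW_ABSENT,
        corneal_reflex=ReflexResponse.BILATERAL_SENSITIVE,
        verbal=Verbal.INCOMPREHENSIBLE_NONE,
        motor_mode=MotorMode.PAIN_RESPONSE,
        motor_pain=MotorPain.FLEXES_EXTENDS,
        swallow=Swallow.WST_III_IV_OR_UNABLE,
        intubated=True,
        vent_interaction=VentInteraction.ABOVE_RATE,
        heart_rate=110,
        sbp=150,
        glucose=12.0,
        sodium=155.0,
        potassium=3.0,
        creatinine=180.0,
        bilirubin=40.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
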