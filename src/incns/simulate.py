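"""Synthetic longitudinal N-ICU cohorts with a controllable
severity-outcome association.

Each patient carries a latent severity ``z ~ N(0,1)``. The 3-month mRS
is drawn from an ordinal-logistic link on ``z`` whose middle threshold
is calibrated so the marginal unfavorable fraction matches the
requested prevalence; observed variables are drawn conditional on ``z``
(not on the outcome), which avoids label leakage and yields realistic,
imperfect discrimination. Readings after 24 h amplify the severity
signal, so 72-h worst-value windows are on average more deranged and
more informative than 24-h windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from . import scoresheet as sh
from .comparators import AdmissionType, SapsChronic
from .scoresheet import Item, MotorMode, MotorPain, VentInteraction
from .valstats import OutcomeRecord
from .windowing import ObservationSeries, score_series

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "calibrate_latent_effect",
    "cohort_scores",
    "ablated_incns_scores",
]

_ADMISSION = datetime(2020, 1, 1, 8, 0, 0)

_ADMISSION_TYPES = (
    AdmissionType.MEDICAL,
    AdmissionType.UNSCHEDULED_SURGICAL,
    AdmissionType.SCHEDULED_SURGICAL,
)
_SAPS_CHRONIC = (
    SapsChronic.NONE,
    SapsChronic.METASTATIC_CANCER,
    SapsChronic.HEMATOLOGIC_MALIGNANCY,
    SapsChronic.AIDS,
)

#: sampling clamps for the unbounded outer bins of each numeric item
_CLAMPS: dict[Item, tuple[float, float]] = {
    Item.WBC: (0.3, 38.0),
    Item.TEMPERATURE: (33.0, 42.0),
    Item.ALBUMIN: (10.0, 52.0),
    Item.GLUCOSE: (0.8, 30.0),
    Item.SODIUM: (108.0, 175.0),
    Item.POTASSIUM: (1.5, 8.5),
    Item.CREATININE: (10.0, 500.0),
    Item.BILIRUBIN: (1.0, 300.0),
    Item.HEART_RATE: (22.0, 190.0),
    Item.SBP: (45.0, 235.0),
    Item.AGE: (16.0, 94.0),
}

#: per-item baseline log-odds of derangement (negative: mostly normal)
_ALPHA = -1.3
#: per-reading noise on the derangement propensity
_NOISE_SD = 0.9

#: relative severity-signal weight per variable: neurologic examination
#: tracks the latent severity more tightly than systemic labs
_WEIGHT: dict[str, float] = {
    "arousal": 1.6,
    "awareness": 1.6,
    "pupillary_reflex": 1.4,
    "corneal_reflex": 1.4,
    "verbal": 1.3,
    "motor": 1.5,
    "swallow": 1.2,
    "respiration": 1.4,
    "consciousness_scales": 1.6,
    "wbc": 0.6,
    "temperature_ax": 0.6,
    "albumin": 0.7,
    "glucose": 0.8,
    "sodium": 0.6,
    "potassium": 0.5,
    "creatinine": 0.6,
    "bilirubin": 0.5,
    "heart_rate": 0.6,
    "sbp": 0.7,
    "oxygenation": 0.9,
    "acid_base": 0.8,
    "hematocrit": 0.5,
    "renal": 0.6,
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    prevalence_unfavorable: float = 0.592
    latent_effect: float = 1.0
    records_per_window: tuple[int, int] = (2, 3)
    missingness_rate: float = 0.0
    seed: int = 0
    #: amplification of the severity signal in post-24 h readings
    late_gain: float = 1.6
    #: latent -> outcome link strength on the logit scale
    outcome_effect: float = 3.5

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.prevalence_unfavorable < 1.0:
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0, 1)")
        lo, hi = self.records_per_window
        if lo < 1 or hi < lo:
            raise ValueError("records_per_window must be a (lo, hi) range with lo >= 1")


@dataclass(frozen=True)
class SyntheticCohort:
    series: tuple[ObservationSeries, ...]
    outcomes: tuple[OutcomeRecord, ...]
    truth: dict


# --------------------------------------------------------------------------
# outcome link calibration


def _marginal_prevalence(tau: float, effect: float) -> float:
    # E_z[ sigmoid(effect*z - tau) ], z ~ N(0,1), Gauss-Hermite
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    p = _sigmoid(effect * nodes - tau)
    return float((weights * p).sum() / math.sqrt(2.0 * math.pi))


def _calibrate_tau(prevalence: float, effect: float) -> float:
    return float(
        optimize.brentq(lambda t: _marginal_prevalence(t, effect) - prevalence, -40, 40)
    )


# --------------------------------------------------------------------------
# per-variable samplers


def _sample_numeric(item: Item, level: int, rng: np.random.Generator) -> float:
    spec = sh.NUMERIC_BINS[item]
    cands = [b for b in spec["bins"] if b[2] == level]
    if len(cands) > 1:  # low/high branches; favor the high-side derangement
        b = cands[1] if rng.random() < 0.7 else cands[0]
    else:
        b = cands[0]
    lo, hi, _ = b
    clamp_lo, clamp_hi = _CLAMPS[item]
    lo = clamp_lo if lo is None else float(lo)
    hi = clamp_hi if hi is None else float(hi)
    v = rng.uniform(lo, hi)
    return round(v, spec["precision"])


def _level(rng, m, propensity) -> int:
    return int(rng.binomial(m, propensity))


def _categorical_by_level(item: Item, level: int):
    table = sh.CATEGORICAL_POINTS[item]
    ordered = sorted(table, key=table.get)
    return ordered[level]


# --------------------------------------------------------------------------
# cohort generation


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate observation series, outcomes and ground truth.

    Deterministic under a fixed spec (the seed fixes the full output).
    """
    rng = np.random.default_rng(spec.seed)
    tau3 = _calibrate_tau(spec.prevalence_unfavorable, spec.outcome_effect)
    mrs_taus = np.array([tau3 + 1.1 * (j - 3) for j in range(1, 7)])

    series = []
    outcomes = []
    zs = np.empty(spec.n_patients)
    lo, hi = spec.records_per_window

    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        z = rng.normal()
        zs[i] = z

        u = spec.outcome_effect * z + rng.logistic()
        mrs = int((u > mrs_taus).sum())
        outcomes.append(OutcomeRecord(patient_id=pid, mrs_3month=mrs))

        age = int(np.clip(rng.normal(51, 17), *_CLAMPS[Item.AGE]))
        statics = {
            "age": age,
            "acute_renal_failure": bool(rng.random() < 0.05),
            "severe_chronic_condition": bool(rng.random() < 0.12),
            "admission_type": _ADMISSION_TYPES[
                rng.choice(len(_ADMISSION_TYPES), p=[0.78, 0.12, 0.10])
            ],
            "saps_chronic": _SAPS_CHRONIC[
                rng.choice(len(_SAPS_CHRONIC), p=[0.92, 0.03, 0.03, 0.02])
            ],
        }

        n_early = int(rng.integers(lo, hi + 1))
        n_late = int(rng.integers(lo, hi + 1))
        t_early = np.sort(rng.uniform(0.5, 24.0, n_early))
        t_late = np.sort(rng.uniform(24.01, 72.0, n_late))

        records = []
        for t, late in [(t, False) for t in t_early] + [(t, True) for t in t_late]:
            gain = spec.late_gain if late else 1.0
            values = _sample_reading(rng, z * gain, spec.latent_effect, statics)
            if spec.missingness_rate > 0:
                values = {
                    k: v
                    for k, v in values.items()
                    if k in statics or rng.random() >= spec.missingness_rate
                }
            records.append((_ADMISSION + timedelta(hours=float(t)), values))
        series.append(
            ObservationSeries(patient_id=pid, admission_time=_ADMISSION, records=tuple(records))
        )

    truth = {
        "z": zs.tolist(),
        "mrs_thresholds": mrs_taus.tolist(),
        "outcome_effect": spec.outcome_effect,
        "latent_effect": spec.latent_effect,
        "late_gain": spec.late_gain,
        "prevalence_unfavorable": spec.prevalence_unfavorable,
        "seed": spec.seed,
    }
    return SyntheticCohort(series=tuple(series), outcomes=tuple(outcomes), truth=truth)


def _propensity(rng, z_eff: float, effect: float, weight: float = 1.0) -> float:
    return float(_sigmoid(_ALPHA + effect * weight * z_eff + rng.normal(0.0, _NOISE_SD)))


def _sample_reading(rng, z_eff: float, effect: float, statics: dict) -> dict:
    values = dict(statics)

    for item, fieldname in (
        (Item.WBC, "wbc"),
        (Item.TEMPERATURE, "temperature_ax"),
        (Item.ALBUMIN, "albumin"),
        (Item.GLUCOSE, "glucose"),
        (Item.SODIUM, "sodium"),
        (Item.POTASSIUM, "potassium"),
        (Item.CREATININE, "creatinine"),
        (Item.BILIRUBIN, "bilirubin"),
        (Item.HEART_RATE, "heart_rate"),
        (Item.SBP, "sbp"),
    ):
        m = sh.ITEM_MAX[item]
        lv = _level(rng, m, _propensity(rng, z_eff, effect, _WEIGHT[fieldname]))
        v = _sample_numeric(item, lv, rng)
        if fieldname in ("heart_rate", "sbp"):
            v = int(v)
        values[fieldname] = v

    for item, fieldname in (
        (Item.AROUSAL, "arousal"),
        (Item.AWARENESS, "awareness"),
        (Item.PUPILLARY_REFLEX, "pupillary_reflex"),
        (Item.CORNEAL_REFLEX, "corneal_reflex"),
        (Item.VERBAL, "verbal"),
        (Item.SWALLOW, "swallow"),
    ):
        n_levels = len(sh.CATEGORICAL_POINTS[item]) - 1
        lv = _level(rng, n_levels, _propensity(rng, z_eff, effect, _WEIGHT[fieldname]))
        values[fieldname] = _categorical_by_level(item, lv)

    # motor: severe patients get the pain-response test
    p_motor = _propensity(rng, z_eff, effect, _WEIGHT["motor"])
    p_cons = _propensity(rng, z_eff, effect, _WEIGHT["consciousness_scales"])
    if rng.random() < _sigmoid(-0.5 + effect * z_eff):
        lv = _level(rng, 3, p_motor)
        values["motor_mode"] = MotorMode.PAIN_RESPONSE
        values["motor_pain"] = list(MotorPain)[lv]
    else:
        lv = _level(rng, 3, p_motor)
        values["motor_mode"] = MotorMode.STRENGTH_TEST
        if lv == 0:
            values["motor_strength_worst"] = int(rng.integers(4, 6))
            values["motor_strength_unilateral_low"] = False
        elif lv == 1:
            values["motor_strength_worst"] = int(rng.integers(2, 4))
            values["motor_strength_unilateral_low"] = False
        else:
            values["motor_strength_worst"] = int(rng.integers(0, 2))
            values["motor_strength_unilateral_low"] = lv == 2

    # respiration
    lv = _level(rng, 3, _propensity(rng, z_eff, effect, _WEIGHT["respiration"]))
    if lv == 0:
        values["intubated"] = False
        values["resp_rate"] = int(rng.integers(12, 25))
    elif lv == 1:
        values["intubated"] = False
        values["resp_rate"] = int(rng.integers(6, 12) if rng.random() < 0.4 else rng.integers(25, 41))
    elif lv == 2:
        values["intubated"] = True
        values["vent_interaction"] = VentInteraction.ABOVE_RATE
        values["resp_rate"] = int(rng.integers(26, 40))
    else:
        values["intubated"] = True
        values["vent_interaction"] = VentInteraction.AT_RATE_OR_APNEA
        values["resp_rate"] = int(rng.integers(12, 20))

    # comparator-only physiology
    values["map_pressure"] = float(np.clip(values["sbp"] * 0.7 + rng.normal(5.0, 5.0), 30, 210))

    oxy = _level(rng, 2, _propensity(rng, z_eff, effect, _WEIGHT["oxygenation"]))
    values["paco2"] = round(float(rng.uniform(33, 47)), 1)
    if oxy == 0:
        values["fio2"] = 0.21
        values["pao2"] = round(float(rng.uniform(78, 100)), 1)
    elif oxy == 1:
        values["fio2"] = 0.4
        values["pao2"] = round(float(rng.uniform(60, 76)), 1)
    else:
        values["fio2"] = round(float(rng.uniform(0.5, 0.9)), 2)
        values["pao2"] = round(float(rng.uniform(52, 70)), 1)

    acid = _level(rng, 2, _propensity(rng, z_eff, effect, _WEIGHT["acid_base"]))
    ph_ranges = [(7.36, 7.44), (7.25, 7.35), (7.10, 7.24)]
    hco3_ranges = [(22.0, 30.0), (18.0, 21.9), (12.0, 17.9)]
    values["arterial_ph"] = round(float(rng.uniform(*ph_ranges[acid])), 2)
    values["hco3"] = round(float(rng.uniform(*hco3_ranges[acid])), 1)

    hct = _level(rng, 2, _propensity(rng, z_eff, effect, _WEIGHT["hematocrit"]))
    hct_ranges = [(35.0, 45.0), (27.0, 34.0), (18.0, 26.0)]
    values["hematocrit"] = round(float(rng.uniform(*hct_ranges[hct])), 1)

    renal = _level(rng, 2, _propensity(rng, z_eff, effect, _WEIGHT["renal"]))
    urine_ranges = [(1200.0, 3000.0), (500.0, 1100.0), (100.0, 450.0)]
    bun_ranges = [(8.0, 25.0), (28.0, 80.0), (85.0, 150.0)]
    values["urine_output_24h"] = round(float(rng.uniform(*urine_ranges[renal])), 0)
    values["bun"] = round(float(rng.uniform(*bun_ranges[renal])), 1)

    # consciousness scales share the consciousness propensity
    values["gcs_eye"] = 4 - _level(rng, 3, p_cons)
    values["gcs_verbal"] = 5 - _level(rng, 4, p_cons)
    values["gcs_motor"] = 6 - _level(rng, 5, p_cons)
    values["four_eye"] = 4 - _level(rng, 4, p_cons)
    values["four_motor"] = 4 - _level(rng, 4, p_cons)
    values["four_brainstem"] = 4 - _level(rng, 4, p_cons)
    values["four_respiration"] = 4 - _level(rng, 4, p_cons)

    return values


# --------------------------------------------------------------------------
# pipeline helpers


def cohort_scores(
    cohort: SyntheticCohort,
    window_hours: int,
    score: str = "incns",
    assume_normal: bool = False,
):
    """Windowed totals + outcome labels, aligned by patient."""
    totals = np.empty(len(cohort.series), dtype=float)
    labels = np.empty(len(cohort.series), dtype=bool)
    by_id = {o.patient_id: o for o in cohort.outcomes}
    for i, s in enumerate(cohort.series):
        totals[i], _, _ = score_series(s, window_hours, score, assume_normal)
        labels[i] = by_id[s.patient_id].unfavorable
    return totals, labels


_DEFAULT_ABLATED = (
    Item.AROUSAL,
    Item.AWARENESS,
    Item.PUPILLARY_REFLEX,
    Item.MOTOR,
    Item.RESPIRATION,
)


def ablated_incns_scores(
    cohort: SyntheticCohort,
    window_hours: int,
    drop: Sequence[Item] = _DEFAULT_ABLATED,
    assume_normal: bool = False,
):
    """INCNS totals with ``drop`` items zeroed out — a deliberately
    degraded comparator for structural pipeline checks."""
    dropset = set(drop)
    totals = np.empty(len(cohort.series), dtype=float)
    labels = np.empty(len(cohort.series), dtype=bool)
    by_id = {o.patient_id: o for o in cohort.outcomes}
    for i, s in enumerate(cohort.series):
        _, _, result = score_series(s, window_hours, "incns", assume_normal)
        totals[i] = sum(it.points for it in result.items if it.item not in dropset)
        labels[i] = by_id[s.patient_id].unfavorable
    return totals, labels


def calibrate_latent_effect(
    target_auc: float = 0.83,
    n_patients: int = 941,
    window_hours: int = 72,
    seeds: Sequence[int] = (0, 1),
    lo: float = 0.05,
    hi: float = 4.0,
    iterations: int = 9,
    **spec_kwargs,
) -> float:
    """Bisection on the latent effect so the simulated 72-h INCNS AUC
    hits ``target_auc`` (the AUC is monotone in the effect)."""
    from .valstats import roc as _roc

    def mean_auc(effect: float) -> float:
        aucs = []
        for seed in seeds:
            cohort = simulate_cohort(
                CohortSpec(n_patients=n_patients, latent_effect=effect, seed=seed, **spec_kwargs)
            )
            scores_, labels = cohort_scores(cohort, window_hours, "incns")
            aucs.append(_roc(scores_, labels).auc)
        return float(np.mean(aucs))

    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if mean_auc(mid) < target_auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
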