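{
  "resource": "incns-scoresheet-bins",
  "version": "1.0",
  "numeric_items": {
    "wbc": {
      "precision": 1,
      "bins": [
        [null, 2.8, 2],
        [2.9, 3.9, 1],
        [4.0, 10.0, 0],
        [10.1, 25.0, 1],
        [25.1, null, 2]
      ]
    },
    "temperature_ax": {
      "precision": 1,
      "bins": [
        [null, 35.9, 1],
        [36.0, 38.4, 0],
        [38.5, 40.0, 1],
        [40.1, null, 2]
      ]
    },
    "albumin": {
      "precision": 1,
      "bins": [
        [null, 24.9, 2],
        [25.0, 34.9, 1],
        [35.0, null, 0]
      ]
    },
    "age": {
      "precision": 0,
      "bins": [
        [null, 44, 0],
        [45, 64, 1],
        [65, 74, 2],
        [75, null, 3]
      ]
    },
    "heart_rate": {
      "precision": 0,
      "bins": [
        [null, 39, 2],
        [40, 59, 1],
        [60, 100, 0],
        [101, 149, 1],
        [150, null, 2]
      ]
    },
    "sbp": {
      "precision": 0,
      "bins": [
        [null, 69, 2],
        [70, 89, 1],
        [90, 140, 0],
        [141, 199, 1],
        [200, null, 2]
      ]
    },
    "glucose": {
      "precision": 1,
      "bins": [
        [null, 2.1, 2],
        [2.2, 3.8, 1],
        [3.9, 11.1, 0],
        [11.2, 19.3, 1],
        [19.4, null, 2]
      ]
    },
    "sodium": {
      "precision": 0,
      "bins": [
        [null, 119, 2],
        [120, 129, 1],
        [130, 150, 0],
        [151, 159, 1],
        [160, null, 2]
      ]
    },
    "potassium": {
      "precision": 1,
      "bins": [
        [null, 2.4, 2],
        [2.5, 3.4, 1],
        [3.5, 5.5, 0],
        [5.6, 6.9, 1],
        [7.0, null, 2]
      ]
    },
    "creatinine": {
      "precision": 0,
      "bins": [
        [null, 43, 1],
        [44, 132, 0],
        [133, 171, 1],
        [172, null, 2]
      ]
    },
    "bilirubin": {
      "precision": 1,
      "bins": [
        [null, 34.1, 0],
        [34.2, 102.5, 1],
        [102.6, null, 2]
      ]
    }
  },
  "categorical_items": {
    "arousal": {
      "spontaneous": 0,
      "to_verbal": 1,
      "to_pain": 2,
      "none": 3
    },
    "awareness": {
      "correct_response": 0,
      "confused_response": 1,
      "nonreflex_movements": 2,
      "none": 3
    },
    "pupillary_reflex": {
      "bilateral_sensitive": 0,
      "unilateral_slow_absent": 2,
      "bilateral_slow_absent": 3
    },
    "corneal_reflex": {
      "bilateral_sensitive": 0,
      "unilateral_slow_absent": 2,
      "bilateral_slow_absent": 3
    },
    "verbal": {
      "accurate": 0,
      "confused_inappropriate": 1,
      "incomprehensible_none": 2
    },
    "swallow": {
      "wst_I_II": 0,
      "wst_III_IV_or_unable": 1
    },
    "motor_pain": {
      "obeys": 0,
      "localizes_withdraws": 1,
      "flexes_extends": 2,
      "none": 3
    }
  },
  "motor_strength_rule": {
    "grade_ge_4": 0,
    "grade_2_3": 1,
    "grade_le_1_unilateral": 2,
    "grade_le_1_bilateral": 3
  },
  "respiration_rule": {
    "not_intubated_rate_12_24": 0,
    "not_intubated_rate_le_11_or_ge_25": 1,
    "intubated_above_rate": 2,
    "intubated_at_rate_or_apnea": 3
  },
  "categories": {
    "inflammation": ["wbc", "temperature_ax"],
    "nutrition": ["albumin"],
    "consciousness": ["arousal", "awareness"],
    "neurologic_function": [
      "pupillary_reflex",
      "corneal_reflex",
      "verbal",
      "motor",
      "swallow",
      "respiration"
    ],
    "systemic_condition": [
      "age",
      "heart_rate",
      "sbp",
      "glucose",
      "sodium",
      "potassium",
      "creatinine",
      "bilirubin"
    ]
  }
}
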