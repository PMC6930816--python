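{
  "resource": "saps2-point-table",
  "version": "1.0",
  "halfopen_bins": {
    "age": [[null, 40, 0], [40, 60, 7], [60, 70, 12], [70, 75, 15], [75, 80, 16], [80, null, 18]],
    "heart_rate": [[null, 40, 11], [40, 70, 2], [70, 120, 0], [120, 160, 4], [160, null, 7]],
    "sbp": [[null, 70, 13], [70, 100, 5], [100, 200, 0], [200, null, 2]],
    "temperature": [[null, 39.0, 0], [39.0, null, 3]],
    "pao2_fio2": [[null, 100, 11], [100, 200, 9], [200, null, 6]],
    "urine_output_l": [[null, 0.5, 11], [0.5, 1.0, 4], [1.0, null, 0]],
    "bun_mgdl": [[null, 28, 0], [28, 84, 6], [84, null, 10]],
    "wbc": [[null, 1.0, 12], [1.0, 20.0, 0], [20.0, null, 3]],
    "potassium": [[null, 3.0, 3], [3.0, 5.0, 0], [5.0, null, 3]],
    "sodium": [[null, 125, 5], [125, 145, 0], [145, null, 1]],
    "hco3": [[null, 15, 6], [15, 20, 3], [20, null, 0]],
    "bilirubin_umol": [[null, 68.4, 0], [68.4, 102.6, 4], [102.6, null, 9]],
    "gcs": [[null, 6, 26], [6, 9, 13], [9, 11, 7], [11, 14, 5], [14, null, 0]]
  },
  "chronic_disease": {
    "none": 0,
    "metastatic_cancer": 9,
    "hematologic_malignancy": 10,
    "aids": 17
  },
  "admission_type": {
    "scheduled_surgical": 0,
    "medical": 6,
    "unscheduled_surgical": 8
  },
  "oxygenation_rule": "PaO2/FiO2 scored only for ventilated (or CPAP) patients; 0 otherwise"
}
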