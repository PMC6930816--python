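{
  "resource": "apache2-point-table",
  "version": "1.0",
  "bins": {
    "temperature": {
      "precision": 1,
      "bins": [
        [null, 29.9, 4], [30.0, 31.9, 3], [32.0, 33.9, 2], [34.0, 35.9, 1],
        [36.0, 38.4, 0], [38.5, 38.9, 1], [39.0, 40.9, 3], [41.0, null, 4]
      ]
    },
    "map_pressure": {
      "precision": 0,
      "bins": [
        [null, 49, 4], [50, 69, 2], [70, 109, 0], [110, 129, 2],
        [130, 159, 3], [160, null, 4]
      ]
    },
    "heart_rate": {
      "precision": 0,
      "bins": [
        [null, 39, 4], [40, 54, 3], [55, 69, 2], [70, 109, 0],
        [110, 139, 2], [140, 179, 3], [180, null, 4]
      ]
    },
    "resp_rate": {
      "precision": 0,
      "bins": [
        [null, 5, 4], [6, 9, 2], [10, 11, 1], [12, 24, 0],
        [25, 34, 1], [35, 49, 3], [50, null, 4]
      ]
    },
    "aado2": {
      "precision": 0,
      "bins": [[null, 199, 0], [200, 349, 2], [350, 499, 3], [500, null, 4]]
    },
    "pao2": {
      "precision": 0,
      "bins": [[null, 54, 4], [55, 60, 3], [61, 70, 1], [71, null, 0]]
    },
    "arterial_ph": {
      "precision": 2,
      "bins": [
        [null, 7.14, 4], [7.15, 7.24, 3], [7.25, 7.32, 2], [7.33, 7.49, 0],
        [7.5, 7.59, 1], [7.6, 7.69, 3], [7.7, null, 4]
      ]
    },
    "hco3": {
      "precision": 1,
      "bins": [
        [null, 14.9, 4], [15.0, 17.9, 3], [18.0, 21.9, 2], [22.0, 31.9, 0],
        [32.0, 40.9, 1], [41.0, 51.9, 3], [52.0, null, 4]
      ]
    },
    "sodium": {
      "precision": 0,
      "bins": [
        [null, 110, 4], [111, 119, 3], [120, 129, 2], [130, 149, 0],
        [150, 154, 1], [155, 159, 2], [160, 179, 3], [180, null, 4]
      ]
    },
    "potassium": {
      "precision": 1,
      "bins": [
        [null, 2.4, 4], [2.5, 2.9, 2], [3.0, 3.4, 1], [3.5, 5.4, 0],
        [5.5, 5.9, 1], [6.0, 6.9, 3], [7.0, null, 4]
      ]
    },
    "creatinine_mgdl": {
      "precision": 1,
      "bins": [[null, 0.5, 2], [0.6, 1.4, 0], [1.5, 1.9, 2], [2.0, 3.4, 3], [3.5, null, 4]]
    },
    "hematocrit": {
      "precision": 1,
      "bins": [
        [null, 19.9, 4], [20.0, 29.9, 2], [30.0, 45.9, 0], [46.0, 49.9, 1],
        [50.0, 59.9, 2], [60.0, null, 4]
      ]
    },
    "wbc": {
      "precision": 1,
      "bins": [
        [null, 0.9, 4], [1.0, 2.9, 2], [3.0, 14.9, 0], [15.0, 19.9, 1],
        [20.0, 39.9, 2], [40.0, null, 4]
      ]
    },
    "age": {
      "precision": 0,
      "bins": [[null, 44, 0], [45, 54, 2], [55, 64, 3], [65, 74, 5], [75, null, 6]]
    }
  },
  "gcs_points": "15 minus GCS total",
  "chronic_health": {
    "none": 0,
    "severe_elective_postoperative": 2,
    "severe_nonoperative_or_emergency_postoperative": 5
  },
  "acute_renal_failure": "creatinine points doubled"
}
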