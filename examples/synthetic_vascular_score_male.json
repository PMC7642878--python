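{
  "schema_version": 1,
  "model_name": "synthetic-vascular-score",
  "sex": "male",
  "tier": "original",
  "horizon_years": 5.0,
  "baseline_survival": 0.928,
  "means": {
    "log_sbp": 4.921,
    "age": 69.21,
    "smoking": 0.458,
    "diabetes_young": 0.034,
    "diabetes_old": 0.102,
    "cvd_history": 0.143
  },
  "terms": [
    {"name": "age", "transform": "identity", "coefficient": 0.048},
    {"name": "log_sbp", "covariate": "sbp", "transform": "log", "coefficient": 1.85},
    {"name": "smoking", "transform": "indicator", "coefficient": 0.52},
    {
      "name": "diabetes_young",
      "covariate": "diabetes",
      "transform": "indicator",
      "coefficient": 0.95,
      "condition": {"covariate": "age", "op": "<", "value": 65}
    },
    {
      "name": "diabetes_old",
      "covariate": "diabetes",
      "transform": "indicator",
      "coefficient": 0.55,
      "condition": {"covariate": "age", "op": ">=", "value": 65}
    },
    {"name": "cvd_history", "transform": "indicator", "coefficient": 0.40},
    {
      "name": "family_history_stroke",
      "transform": "indicator",
      "coefficient": 0.30,
      "assume_zero_if_missing": true
    }
  ]
}
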