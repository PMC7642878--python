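{
  "schema_version": 1,
  "model_name": "synthetic-vascular-score",
  "sex": "female",
  "tier": "original",
  "horizon_years": 5.0,
  "baseline_survival": 0.936,
  "means": {
    "log_sbp": 4.928,
    "age": 68.15,
    "smoking": 0.075,
    "diabetes_young": 0.054,
    "diabetes_old": 0.128,
    "cvd_history": 0.165
  },
  "terms": [
    {"name": "age", "transform": "identity", "coefficient": 0.051},
    {"name": "log_sbp", "covariate": "sbp", "transform": "log", "coefficient": 2.05},
    {"name": "smoking", "transform": "indicator", "coefficient": 0.48},
    {
      "name": "diabetes_young",
      "covariate": "diabetes",
      "transform": "indicator",
      "coefficient": 1.05,
      "condition": {"covariate": "age", "op": "<", "value": 65}
    },
    {
      "name": "diabetes_old",
      "covariate": "diabetes",
      "transform": "indicator",
      "coefficient": 0.60,
      "condition": {"covariate": "age", "op": ">=", "value": 65}
    },
    {"name": "cvd_history", "transform": "indicator", "coefficient": 0.45},
    {
      "name": "family_history_stroke",
      "transform": "indicator",
      "coefficient": 0.28,
      "assume_zero_if_missing": true
    }
  ]
}
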