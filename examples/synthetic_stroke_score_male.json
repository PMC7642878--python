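{
  "schema_version": 1,
  "model_name": "synthetic-stroke-score",
  "sex": "male",
  "tier": "original",
  "horizon_years": 5.0,
  "baseline_survival": 0.9175942312201509,
  "means": {
    "age": 69.21,
    "sbp": 138.18,
    "total_cholesterol": 214.48,
    "hdl_c": 46.72,
    "smoking": 0.458,
    "diabetes": 0.136,
    "antihypertensive": 0.318,
    "cvd_history": 0.143
  },
  "terms": [
    {
      "name": "age",
      "transform": "identity",
      "coefficient": 0.055
    },
    {
      "name": "sbp",
      "transform": "identity",
      "coefficient": 0.012
    },
    {
      "name": "total_cholesterol",
      "transform": "identity",
      "coefficient": 0.0015
    },
    {
      "name": "hdl_c",
      "transform": "identity",
      "coefficient": -0.018
    },
    {
      "name": "smoking",
      "transform": "indicator",
      "coefficient": 0.4
    },
    {
      "name": "diabetes",
      "transform": "indicator",
      "coefficient": 0.45
    },
    {
      "name": "antihypertensive",
      "transform": "indicator",
      "coefficient": 0.25
    },
    {
      "name": "cvd_history",
      "transform": "indicator",
      "coefficient": 0.35
    }
  ]
}
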