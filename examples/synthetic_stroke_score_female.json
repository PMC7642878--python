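{
  "schema_version": 1,
  "model_name": "synthetic-stroke-score",
  "sex": "female",
  "tier": "original",
  "horizon_years": 5.0,
  "baseline_survival": 0.9254270243966368,
  "means": {
    "age": 68.15,
    "sbp": 139.17,
    "total_cholesterol": 237.91,
    "hdl_c": 47.9,
    "smoking": 0.075,
    "diabetes": 0.182,
    "antihypertensive": 0.44,
    "cvd_history": 0.165
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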