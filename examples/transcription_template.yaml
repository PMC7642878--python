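# Transcription template for a published sex-specific Cox absolute-risk score.
#
# Fill one file per sex from the source publication.  All values come from the
# source; nothing here is estimated by this package.  Units must match the
# cohort columns you will score (age in years, sbp in mmHg, cholesterol in
# mg/dl, ...).  `means` are on the TRANSFORM scale (a log-transformed term's
# mean is the mean of the log).  A term whose covariate your cohort never
# measured (e.g. atrial fibrillation, parental stroke history) may set
# `assume_zero_if_missing: true`; it then contributes 0 to every linear
# predictor, and needs no entry in `means`.

schema_version: 1
model_name: null        # e.g. "my-published-score"
sex: null               # "male" or "female"
tier: original
horizon_years: null     # horizon of baseline_survival, e.g. 10
baseline_survival: null # S0(horizon) at the covariate means, in (0, 1]

means:
  age: null
  # one entry per term name below

terms:
  - name: age
    transform: identity      # identity | log | indicator
    coefficient: null        # log hazard ratio per transformed unit
  - name: example_log_term
    covariate: sbp           # cohort column, when it differs from `name`
    transform: log
    coefficient: null
  - name: example_conditional_indicator
    covariate: diabetes
    transform: indicator
    coefficient: null
    condition: {covariate: age, op: "<", value: 65}
  - name: example_unmeasured_predictor
    transform: indicator
    coefficient: null
    assume_zero_if_missing: true
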