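# Overrides for `coxval simulate --config ...`.  Any top-level field of the
# simulation configuration may appear; omitted fields keep the package
# defaults (a ~2,500-subject community cohort of older adults with the default
# covariate marginals, exclusion flags and follow-up structure).
n_total: 2468
admin_censor_years: 5.1
dropout_fraction: 0.125
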