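# Published calibrated coefficients of the weekly recovery (episode
# duration) equation: complementary-log-log hazard with age-group
# dummies (reference: age 12-18) and natural-log episode-clock term.
alpha: -1.31
age_19_25: -0.02
age_26_45: -0.13
age_46_65: -0.33
age_66_plus: -0.35
log_time: -0.53
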