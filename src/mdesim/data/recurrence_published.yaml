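# Published calibrated coefficients of the weekly recurrence log-odds
# equation: intercept, main effects and the 23 printed cross-product
# rows (combinations without a printed row are structural zeros).
Intercept: -6.625
Age 19-25: -0.025
Age 26-45: -0.315
Age 46-65: -0.815
Age 66 or more: -4.0
Pain: 0.40
Smoking: 0.39
Childhood stressor: 0.715
Pain by age 26-45: 0.08
Pain by age 46-65: 0.375
Pain by age 66 or more: 3.02
Smoking by age 26-45: 0.05
Smoking by age 46-65: 0.35
Smoking by age 66 or more: 3.0
Childhood stressor by age 26-45: 0.03
Childhood stressor by age 46-65: 0.45
Childhood stressor by age 66 or more: 3.24
Pain by smoking: 0.12
Pain by smoking by age 19-25: 0.10
Pain by smoking by age 46-65: -0.20
Pain by smoking by age 66 or more: -2.475
Pain by childhood stressor by age 19-25: 0.08
Pain by childhood stressor by age 46-65: -0.14
Pain by childhood stressor by age 66 or more: -2.30
Smoking by childhood stressor by age 46-65: -0.11
Smoking by childhood stressor by age 66 or more: -2.30
Pain by smoking by childhood stressor: -0.035
Pain by smoking by childhood stressor by age 19-25: -0.14
Pain by smoking by childhood stressor by age 26-45: -0.20
Pain by smoking by childhood stressor by age 46-65: -0.075
Pain by smoking by childhood stressor by age 66 or more: 1.705
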