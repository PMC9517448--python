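# Final path model: colorectal cancer screening, female.
# Residual-covariance set reduced to a single pair: the published
# degrees of freedom admit exactly one.  With only two intervention
# indicators, a recall-call residual covariance would leave the
# factor's disturbance unidentified, so the revenue-expense pair is
# the one retained.
resources =~ phns + public_health_expense + general_revenue
interventions =~ recall + call
rate ~ household_income
interventions ~ resources
resources ~ aging_rate
general_revenue ~~ public_health_expense
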