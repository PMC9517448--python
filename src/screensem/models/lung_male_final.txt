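# Final path model: lung cancer screening, male.
# Residual-covariance set reduced to call ~~ recall: the
# published degrees of freedom admit exactly one residual pair.
resources =~ phns + public_health_expense + general_revenue
interventions =~ recall + call + charge_free
rate ~ interventions + aging_rate
interventions ~ resources
resources ~ aging_rate
call ~~ recall
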