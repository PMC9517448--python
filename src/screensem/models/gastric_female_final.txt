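# Final path model: gastric cancer screening, female.
resources =~ phns + public_health_expense + general_revenue
interventions =~ recall + call + upper_limit
rate ~ interventions + household_income
interventions ~ resources
resources ~ aging_rate
call ~~ recall
call ~~ upper_limit
general_revenue ~~ public_health_expense
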