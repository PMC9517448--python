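# Pre-analysis hypothesis model: colorectal cancer screening, female.
# Both latent factors act on the screening rate directly; resource
# indicators not yet pruned.  Intervention indicators exclude the
# variables the normality screen removes for this cancer type.
resources =~ phns + public_health_expense + general_revenue + nurses + hospitals + physicians
interventions =~ recall + call
rate ~ interventions + resources + household_income
interventions ~ resources
resources ~ aging_rate
call ~~ recall
general_revenue ~~ public_health_expense
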