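# Pilot-style normal priors over the 13 encoded utility columns used by the
# Bayesian D-efficiency criterion: modest coefficients in the expected
# directions (higher accuracy, more cancers, site identification and
# early-stage detection preferred; mild dislike of faecal sampling), with a
# common prior variance expressing pilot-scale uncertainty.
mean:
  ppv_20: -1.6
  ppv_40: -1.1
  ppv_60: -0.55
  "npv_96.0": -0.75
  "npv_99.0": -0.32
  "npv_99.5": -0.15
  waiting_1-2_weeks: -0.02
  cancers_per10: 0.19
  site_yes: 0.27
  form_faecal: -0.08
  form_urine: 0.0
  form_breath: 0.0
  early_yes: 0.29
variance: 0.05
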