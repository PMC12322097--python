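# Benchmark and clinical-comparator test profiles.
#
# The SYMPLIFY-like multi-cancer blood test: PPV 76%, NPV 98%, results in
# 1-2 weeks, identifies the cancer site, detects early-stage disease; it
# covers over 50 cancer types, clamped here to the design maximum of 25.
# FIT/PSA/CA125 are single-cancer triage tests; their accuracy entries are
# illustrative placeholders (synthetic), not published operating points.
symplify_mct:
  ppv: 76
  npv: 98.0
  waiting: "1-2 weeks"
  cancers: 50
  site: "yes"
  form: blood
  early: "yes"
  notes: "multi-cancer blood test benchmark; cancers above the design range are clamped to 25"
fit:
  ppv: 20
  npv: 99.0
  waiting: "1 week"
  cancers: 1
  site: "yes"
  form: faecal
  early: "no"
  notes: "faecal immunochemical test (colorectal); illustrative accuracy values"
psa:
  ppv: 25
  npv: 99.0
  waiting: "1 week"
  cancers: 1
  site: "yes"
  form: blood
  early: "no"
  notes: "prostate-specific antigen blood test; illustrative accuracy values"
ca125:
  ppv: 20
  npv: 99.5
  waiting: "1 week"
  cancers: 1
  site: "yes"
  form: blood
  early: "no"
  notes: "CA125 ovarian blood marker; illustrative accuracy values"
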