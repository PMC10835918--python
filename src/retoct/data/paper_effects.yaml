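# Injected-eye fractional thickness multipliers by post-injection day.
# Control eye and day 0 are implicitly 1.0.  With the default baseline layer
# thicknesses (18, 14, 50, 22, 14, 60, 6, 28, 12, 6 um) these give composite
# inner-retina changes of -10.5% (day 7) and -15.8% (day 28), and outer-retina
# changes of -3.9% (day 7) and +5.5% (day 28).
multipliers:
  ILM-RNFL: {0: 1.0, 3: 1.10, 7: 1.00, 28: 0.85}
  GCL:      {0: 1.0, 3: 1.04, 7: 0.98, 28: 0.90}
  IPL:      {0: 1.0, 3: 0.88, 7: 0.75, 28: 0.70}
  INL:      {0: 1.0, 3: 0.98, 7: 0.88, 28: 0.82}
  OPL:      {0: 1.0, 3: 1.02, 7: 0.98, 28: 1.00}
  ONL:      {0: 1.0, 3: 1.01, 7: 0.9502, 28: 0.9156}
  ELM:      {0: 1.0, 3: 0.92, 7: 0.90, 28: 1.00}
  PRL:      {0: 1.0, 3: 1.00, 7: 0.992, 28: 1.12}
  RPE:      {0: 1.0, 3: 0.96, 7: 0.94, 28: 1.00}
  BM:       {0: 1.0, 3: 0.92, 7: 0.92, 28: 0.92}
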