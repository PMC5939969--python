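# Site-type -> ionizable-group pKas contributed by a modification.
# The phosphate monoester is diprotic: two acidic groups per site.
# Values stated for phospho-S/T; phospho-Y reuses them (documented choice).
phospho:
  polarity: acid
  pkas: [1.2, 6.5]
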