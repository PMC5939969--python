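name: emboss
source: "EMBOSS suite iep defaults; Rice, P., Longden, I. & Bleasby, A. (2000) Trends Genet. 16, 276-277"
n_term: 8.6
c_term: 3.6
sidechain:
  C: 8.5
  D: 3.9
  E: 4.1
  H: 6.5
  K: 10.8
  R: 12.5
  Y: 10.1
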