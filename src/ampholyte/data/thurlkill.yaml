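name: thurlkill
source: "Thurlkill, R.L. et al. (2006) Protein Sci. 15, 1214-1218"
n_term: 8.0
c_term: 3.67
sidechain:
  C: 8.55
  D: 3.67
  E: 4.25
  H: 6.54
  K: 10.4
  R: 12.0
  Y: 9.84
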