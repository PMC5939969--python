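name: rodwell
source: "Rodwell, J.D. (1982) Anal. Biochem. 119, 440-449"
n_term: 8.0
c_term: 3.1
sidechain:
  C: 8.33
  D: 3.68
  E: 4.25
  H: 6.0
  K: 11.5
  R: 11.5
  Y: 10.07
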