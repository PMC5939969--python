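name: toseland
source: "Toseland, C.P., McSparron, H., Davies, M.N. & Flower, D.R. (2006) Nucleic Acids Res. 34, D199-D203 (PPD)"
n_term: 8.71
c_term: 3.19
sidechain:
  C: 6.87
  D: 3.6
  E: 4.29
  H: 6.33
  K: 10.45
  R: 12.0
  Y: 9.61
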