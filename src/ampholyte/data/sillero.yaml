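name: sillero
source: "Sillero, A. & Ribeiro, J.M. (1989) Anal. Biochem. 179, 319-325"
n_term: 8.2
c_term: 3.2
sidechain:
  C: 9.0
  D: 4.0
  E: 4.5
  H: 6.4
  K: 10.4
  R: 12.0
  Y: 10.0
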