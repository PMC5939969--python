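name: grimsley
source: "Grimsley, G.R., Scholtz, J.M. & Pace, C.N. (2009) Protein Sci. 18, 247-251"
n_term: 7.7
c_term: 3.3
sidechain:
  C: 6.8
  D: 3.5
  E: 4.2
  H: 6.6
  K: 10.5
  R: 12.04
  Y: 10.3
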