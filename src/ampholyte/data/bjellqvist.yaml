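# Sidechain basis underlying the position-aware Bjellqvist terminal variants;
# also usable directly by the iterative/cofactor/branca solvers.
name: bjellqvist
source: "Bjellqvist, B. et al. (1993) Electrophoresis 14, 1023-1031"
n_term: 7.5
c_term: 3.55
sidechain:
  C: 9.0
  D: 4.05
  E: 4.45
  H: 5.98
  K: 10.0
  R: 12.0
  Y: 10.0
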