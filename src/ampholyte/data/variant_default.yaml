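# Position-aware terminal pKa tables of the original Bjellqvist method:
# the alpha-amino pKa depends on the identity of residue 1, and C-terminal
# D/E sidechains take raised pKas.
name: default
source: "Bjellqvist, B. et al. (1993) Electrophoresis 14, 1023-1031"
base_set: bjellqvist
n_term_by_residue:
  A: 7.59
  M: 7.0
  S: 6.93
  P: 8.36
  T: 6.82
  V: 7.44
  E: 7.7
  G: 7.5
c_term_by_residue: {}
sidechain_positional:
  - {residue: D, context: c-terminal, pka: 4.55}
  - {residue: E, context: c-terminal, pka: 4.75}
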