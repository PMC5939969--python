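# The ExPASy Compute pI/Mw rendition of the Bjellqvist tables: same
# residue-dependent alpha-amino pKas, no positional sidechain adjustments.
name: expasy
source: "Gasteiger, E. et al. (2003) Nucleic Acids Res. 31, 3784-3788 (ExPASy Compute pI/Mw)"
base_set: bjellqvist
n_term_by_residue:
  A: 7.59
  M: 7.0
  S: 6.93
  P: 8.36
  T: 6.82
  V: 7.44
  E: 7.7
c_term_by_residue: {}
sidechain_positional: []
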