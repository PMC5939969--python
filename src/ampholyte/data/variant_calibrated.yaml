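# Terminal pKas recalibrated against peptide IEF measurements.
name: calibrated
source: "Gauci, S. et al. (2008) Proteomics 8, 4898-4906 (IEF-calibrated termini)"
base_set: bjellqvist
n_term_by_residue:
  A: 7.18
  M: 6.98
  S: 6.86
  P: 8.36
  T: 7.02
  V: 7.44
  E: 7.58
  G: 7.5
c_term_by_residue: {}
sidechain_positional:
  - {residue: D, context: c-terminal, pka: 4.55}
  - {residue: E, context: c-terminal, pka: 4.75}
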