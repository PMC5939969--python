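# SYNTHETIC stand-in correction table for the Cofactor method.
# The primary publication's fitted dpKa constants (Cargile, B.J. et al.,
# J. Proteome Res.) are not bundled; these entries are constructed defaults
# with plausible sign and magnitude (basic neighbors stabilize the carboxylate
# anion and lower acid pKas; acidic neighbors raise them; effects decay with
# distance). Users should replace this file with transcribed constants for
# production use. Corrections apply to D/E sidechains and the C-terminus only.
method: cofactor
window: 3
source: "synthetic defaults in the spirit of Cargile, B.J. et al. (2008) J. Proteome Res. 7, 3685-3695"
entries:
  - {residue: K, offset: -1, delta: -0.24}
  - {residue: K, offset: 1, delta: -0.24}
  - {residue: K, offset: -2, delta: -0.12}
  - {residue: K, offset: 2, delta: -0.12}
  - {residue: K, offset: -3, delta: -0.06}
  - {residue: K, offset: 3, delta: -0.06}
  - {residue: R, offset: -1, delta: -0.26}
  - {residue: R, offset: 1, delta: -0.26}
  - {residue: R, offset: -2, delta: -0.13}
  - {residue: R, offset: 2, delta: -0.13}
  - {residue: R, offset: -3, delta: -0.07}
  - {residue: R, offset: 3, delta: -0.07}
  - {residue: H, offset: -1, delta: -0.10}
  - {residue: H, offset: 1, delta: -0.10}
  - {residue: H, offset: -2, delta: -0.05}
  - {residue: H, offset: 2, delta: -0.05}
  - {residue: D, offset: -1, delta: 0.16}
  - {residue: D, offset: 1, delta: 0.16}
  - {residue: D, offset: -2, delta: 0.08}
  - {residue: D, offset: 2, delta: 0.08}
  - {residue: D, offset: -3, delta: 0.04}
  - {residue: D, offset: 3, delta: 0.04}
  - {residue: E, offset: -1, delta: 0.14}
  - {residue: E, offset: 1, delta: 0.14}
  - {residue: E, offset: -2, delta: 0.07}
  - {residue: E, offset: 2, delta: 0.07}
  - {residue: E, offset: -3, delta: 0.03}
  - {residue: E, offset: 3, delta: 0.03}
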