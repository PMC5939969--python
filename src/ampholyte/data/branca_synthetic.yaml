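# SYNTHETIC stand-in correction table for the Branca method.
# The primary publication's constants (Branca et al.) are not bundled; these
# are constructed defaults with plausible magnitudes, decaying over the
# six-residue window. Each entry is weighted at solve time by the charged
# fraction of the neighboring ionizable group. The carboxyl correction is an
# additive term on D/E sidechain pKas keyed by (count of D, count of E).
# Replace with transcribed constants for production use.
method: branca
window: 6
source: "synthetic defaults in the spirit of Branca, R.M.M. et al. (2014) Nat. Methods 11, 59-62 (HiRIEF)"
entries:
  - {residue: K, offset: -1, delta: -0.20}
  - {residue: K, offset: 1, delta: -0.20}
  - {residue: K, offset: -2, delta: -0.10}
  - {residue: K, offset: 2, delta: -0.10}
  - {residue: K, offset: -3, delta: -0.06}
  - {residue: K, offset: 3, delta: -0.06}
  - {residue: K, offset: -4, delta: -0.04}
  - {residue: K, offset: 4, delta: -0.04}
  - {residue: K, offset: -5, delta: -0.02}
  - {residue: K, offset: 5, delta: -0.02}
  - {residue: K, offset: -6, delta: -0.01}
  - {residue: K, offset: 6, delta: -0.01}
  - {residue: R, offset: -1, delta: -0.22}
  - {residue: R, offset: 1, delta: -0.22}
  - {residue: R, offset: -2, delta: -0.11}
  - {residue: R, offset: 2, delta: -0.11}
  - {residue: R, offset: -3, delta: -0.06}
  - {residue: R, offset: 3, delta: -0.06}
  - {residue: R, offset: -4, delta: -0.04}
  - {residue: R, offset: 4, delta: -0.04}
  - {residue: R, offset: -5, delta: -0.02}
  - {residue: R, offset: 5, delta: -0.02}
  - {residue: R, offset: -6, delta: -0.01}
  - {residue: R, offset: 6, delta: -0.01}
  - {residue: D, offset: -1, delta: 0.14}
  - {residue: D, offset: 1, delta: 0.14}
  - {residue: D, offset: -2, delta: 0.07}
  - {residue: D, offset: 2, delta: 0.07}
  - {residue: D, offset: -3, delta: 0.04}
  - {residue: D, offset: 3, delta: 0.04}
  - {residue: E, offset: -1, delta: 0.12}
  - {residue: E, offset: 1, delta: 0.12}
  - {residue: E, offset: -2, delta: 0.06}
  - {residue: E, offset: 2, delta: 0.06}
  - {residue: E, offset: -3, delta: 0.03}
  - {residue: E, offset: 3, delta: 0.03}
carboxyl_correction:
  - {n_d: 2, n_e: 0, delta: 0.05}
  - {n_d: 0, n_e: 2, delta: 0.04}
  - {n_d: 1, n_e: 1, delta: 0.04}
  - {n_d: 2, n_e: 1, delta: 0.08}
  - {n_d: 1, n_e: 2, delta: 0.07}
  - {n_d: 2, n_e: 2, delta: 0.10}
  - {n_d: 3, n_e: 0, delta: 0.09}
  - {n_d: 0, n_e: 3, delta: 0.08}
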