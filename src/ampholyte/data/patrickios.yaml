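# Deliberately coarse basis: only four sidechain entries, with D/E and K/R
# collapsed to shared values. Its poor benchmark accuracy is data, not a
# special code path.
name: patrickios
source: "Patrickios, C.S. & Yamasaki, E.N. (1995) Anal. Biochem. 231, 82-91"
n_term: 11.2
c_term: 4.2
sidechain:
  D: 4.2
  E: 4.2
  K: 11.2
  R: 11.2
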