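# Iterative-method pKa basis set.
name: solomon
source: "Solomon, T.W.G. (1998) Fundamentals of Organic Chemistry, 5th ed."
n_term: 9.6
c_term: 2.4
sidechain:
  C: 8.3
  D: 3.9
  E: 4.3
  H: 6.0
  K: 10.5
  R: 12.5
  Y: 10.1
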