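name: lehninger
source: "Nelson, D.L. & Cox, M.M. (2000) Lehninger Principles of Biochemistry, 3rd ed."
n_term: 9.69
c_term: 2.34
sidechain:
  C: 8.33
  D: 3.86
  E: 4.25
  H: 6.0
  K: 10.5
  R: 12.4
  Y: 10.0
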