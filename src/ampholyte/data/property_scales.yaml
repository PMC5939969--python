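# Per-residue numeric property scales for sequence featurization, in the
# style of AAindex entries. Aggregated as the sequence mean.
kd_hydropathy:
  source: "Kyte, J. & Doolittle, R.F. (1982) J. Mol. Biol. 157, 105-132"
  values:
    A: 1.8
    R: -4.5
    N: -3.5
    D: -3.5
    C: 2.5
    Q: -3.5
    E: -3.5
    G: -0.4
    H: -3.2
    I: 4.5
    L: 3.8
    K: -3.9
    M: 1.9
    F: 2.8
    P: -1.6
    S: -0.8
    T: -0.7
    W: -0.9
    Y: -1.3
    V: 4.2
residue_mass:
  source: "monoisotopic residue masses (Da)"
  values:
    A: 71.03711
    R: 156.10111
    N: 114.04293
    D: 115.02694
    C: 103.00919
    E: 129.04259
    Q: 128.05858
    G: 57.02146
    H: 137.05891
    I: 113.08406
    L: 113.08406
    K: 128.09496
    M: 131.04049
    F: 147.06841
    P: 97.05276
    S: 87.03203
    T: 101.04768
    W: 186.07931
    Y: 163.06333
    V: 99.06841
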