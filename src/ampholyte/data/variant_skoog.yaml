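# Uniform (residue-independent) terminal pKas; no positional adjustments.
name: skoog
source: "Skoog, B. & Wichman, A. (1986) Trends Anal. Chem. 5, 82-83"
base_set: skoog_base
n_term_by_residue: {}
c_term_by_residue: {}
sidechain_positional: []
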