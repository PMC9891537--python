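# High cis ligand; vary its dimerization rate (dimer-deficient ligands fail
# to cis-inhibit under C1).
kind: dimerization-sweep
model: C1
fixed_b_L: 4000
ext: {L_ext: 1500}
sweep: {param: k_d, start: 1.0e-8, stop: 1.0e-3, num: 21, log: true}
normalized: false
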