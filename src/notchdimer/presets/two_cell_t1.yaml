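# Two identical coupled cells, monomer trans / dimer cis kinetics.
kind: two-cell
model: T1
sweep: {param: b_L, start: 0, stop: 4000, num: 21}
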