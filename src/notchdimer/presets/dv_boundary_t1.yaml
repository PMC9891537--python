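# Dorsal Serrate / ventral Delta with binary Fringe gating.
kind: lattice
lattice: {kind: dv-boundary, rows: 20, cols: 20, model: T1, b_N: 1000, b_L: 200}
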