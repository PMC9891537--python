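# Exponential ligand gradient across rows; two flanking activity bands.
kind: lattice
lattice: {kind: wing-vein, rows: 20, cols: 20, model: T1, L_max: 15000}
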