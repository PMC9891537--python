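kind: dimerization-sweep
model: T1
fixed_b_L: 4000
sweep: {param: k_d, start: 1.0e-8, stop: 1.0e-3, num: 21, log: true}
normalized: false
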