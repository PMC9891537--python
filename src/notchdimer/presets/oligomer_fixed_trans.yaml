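kind: oligomer
setting: fixed-trans
n: 3
sweep: {param: b_L, start: 10, stop: 20000, num: 15, log: true}
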