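kind: cis-activation
model: CIS-ACTIVATION
scenario: 3
sweep: {param: b_L, start: 10, stop: 20000, num: 21, log: true}
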