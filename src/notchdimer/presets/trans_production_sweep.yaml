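# Sending cell's ligand production varies; receiver solved jointly.
kind: sweep
model: T1
sweep: {param: b_L, start: 0, stop: 4000, num: 21}
normalized: false
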