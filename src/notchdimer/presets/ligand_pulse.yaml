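# Cell pre-loaded with ligand (mostly dimers), production off, trans bath on:
# delayed-onset activity while the dimer store titrates de-novo receptor.
kind: pulse
model: T1
ext: {L_ext: 1500}
simulate: {init: [500, 9500, 0, 0], t_end: 100, num: 201}
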