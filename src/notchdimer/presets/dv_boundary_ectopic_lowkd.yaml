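kind: lattice
lattice:
  kind: dv-boundary
  model: T1
  ectopic: {species: Delta, center: 4, L_max: 15000, k_d: 1.0e-7}
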