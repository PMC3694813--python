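{
  "block_system": {
    "n_blocks": 2,
    "atoms_per_block": 14,
    "hinge_atoms": 4,
    "stiff_k": 5.0,
    "soft_k": 0.5,
    "seed": 7
  }
}
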