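light: false
beta_A: 1.0
beta_B: 0.0
beta_glu: 0.0
onset_min: 50.0
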