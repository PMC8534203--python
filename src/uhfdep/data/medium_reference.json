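{
  "eps_r": 78.0,
  "sigma_S_per_m": 0.02
}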