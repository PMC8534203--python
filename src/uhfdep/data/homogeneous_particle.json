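{
  "radius_um": 5.0,
  "membrane_thickness_nm": 50.0,
  "membrane": {
    "eps_r": 60.0,
    "sigma_S_per_m": 0.01
  },
  "interior": {
    "eps_r": 60.0,
    "sigma_S_per_m": 0.01
  }
}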