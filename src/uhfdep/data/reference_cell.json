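{
  "radius_um": 11.5,
  "membrane_thickness_nm": 700.0,
  "membrane": {
    "eps_r": 100.0,
    "sigma_S_per_m": 0.000143
  },
  "interior": {
    "eps_r": 50.0,
    "sigma_S_per_m": 0.5
  }
}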