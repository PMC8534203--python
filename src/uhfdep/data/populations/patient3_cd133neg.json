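{
  "label": "P3-CD133neg",
  "n_cells": 50,
  "fx01": {
    "median_khz": 81,
    "sd_khz": 31.12
  },
  "fx02": {
    "median_mhz": 225,
    "sd_mhz": 72.66
  },
  "medium": {
    "eps_r": 78.0,
    "sigma_S_per_m": 0.026
  },
  "note": "synthetic default spread: SD = median x U87-MG NM SD/median ratio; per-patient n and SD were not reported"
}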