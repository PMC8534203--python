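{
  "label": "P1-CD133neg",
  "n_cells": 50,
  "fx01": {
    "median_khz": 88,
    "sd_khz": 33.8
  },
  "fx02": {
    "median_mhz": 229,
    "sd_mhz": 73.95
  },
  "medium": {
    "eps_r": 78.0,
    "sigma_S_per_m": 0.026
  },
  "note": "synthetic default spread: SD = median x U87-MG NM SD/median ratio; per-patient n and SD were not reported"
}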