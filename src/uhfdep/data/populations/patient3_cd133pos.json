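{
  "label": "P3-CD133pos",
  "n_cells": 50,
  "fx01": {
    "median_khz": 70,
    "sd_khz": 26.89
  },
  "fx02": {
    "median_mhz": 92,
    "sd_mhz": 29.71
  },
  "medium": {
    "eps_r": 78.0,
    "sigma_S_per_m": 0.026
  },
  "note": "synthetic default spread: SD = median x U87-MG NM SD/median ratio; per-patient n and SD were not reported"
}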