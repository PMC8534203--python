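{
  "label": "P2-CD133pos",
  "n_cells": 50,
  "fx01": {
    "median_khz": 83,
    "sd_khz": 31.88
  },
  "fx02": {
    "median_mhz": 86,
    "sd_mhz": 27.77
  },
  "medium": {
    "eps_r": 78.0,
    "sigma_S_per_m": 0.026
  },
  "note": "synthetic default spread: SD = median x U87-MG NM SD/median ratio; per-patient n and SD were not reported"
}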