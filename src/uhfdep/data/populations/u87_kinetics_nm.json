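{
  "label": "NM",
  "n_cells": 150,
  "fx01": {
    "median_khz": 82.0,
    "sd_khz": 31.5
  },
  "fx02": {
    "median_mhz": 108.0,
    "sd_mhz": 36.2
  },
  "medium": {
    "eps_r": 78.0,
    "sigma_S_per_m": 0.026
  },
  "note": "fx01 row: first-campaign NM values (kinetics campaign printed fx02 only)"
}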