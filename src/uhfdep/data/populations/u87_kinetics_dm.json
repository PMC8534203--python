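{
  "label": "DM",
  "n_cells": 150,
  "fx01": {
    "median_khz": 74.0,
    "sd_khz": 32.1
  },
  "fx02": {
    "median_mhz": 88.0,
    "sd_mhz": 27.9
  },
  "medium": {
    "eps_r": 78.0,
    "sigma_S_per_m": 0.026
  },
  "note": "fx01 row: first-campaign DM values (kinetics campaign printed fx02 only)"
}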