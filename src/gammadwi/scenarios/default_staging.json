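{
  "name": "default_staging",
  "seed": 0,
  "protocol": "fixed-theta",
  "percent": false,
  "b_values_s_per_mm2": [
    0.0,
    500.0,
    1000.0,
    1500.0,
    2000.0
  ],
  "noise": {
    "model": "rician",
    "snr": 50.0
  },
  "thresholds_mm2_per_s": {
    "staging_low": 0.0001,
    "staging_high": 0.0003,
    "grading": [
      3e-05,
      5e-05,
      8e-05
    ]
  },
  "groups": [
    {
      "label": "meningioma",
      "n_subjects": 24,
      "kappa_mean": 0.0623,
      "kappa_sd": 0.021,
      "theta_mean": 74.55,
      "theta_sd": 5.5,
      "s0_mean": 1000.0,
      "s0_sd": 100.0,
      "kappa_floor": 0.0001,
      "theta_floor": 1.0,
      "s0_floor": 1.0
    },
    {
      "label": "glioma",
      "n_subjects": 42,
      "kappa_mean": 0.0394,
      "kappa_sd": 0.038,
      "theta_mean": 74.54,
      "theta_sd": 6.1,
      "s0_mean": 1000.0,
      "s0_sd": 100.0,
      "kappa_floor": 0.0001,
      "theta_floor": 1.0,
      "s0_floor": 1.0
    }
  ]
}
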