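{
  "region": "Tokyo",
  "total_patients": 4873585,
  "sex_proportions": {"male": 0.561, "female": 0.439},
  "condition_proportions": {"UC": 0.565, "CD": 0.435},
  "age_targets": {
    "UC": {
      "male": {"mean": 52.7, "sd": 15.5},
      "female": {"mean": 52.0, "sd": 15.6}
    },
    "CD": {
      "male": {"mean": 61.4, "sd": 8.3},
      "female": {"mean": 52.2, "sd": 16.9}
    }
  },
  "age_bounds": [18, 74],
  "severity_proportions": {"mild_moderate": 0.7, "moderate_severe": 0.3},
  "initial_diagnosed_fraction": 0.7,
  "initial_biologic_fraction": 0.15
}
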