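{
  "region": "Hokkaido",
  "total_patients": 438983,
  "sex_proportions": {"male": 0.445, "female": 0.555},
  "condition_proportions": {"UC": 0.731, "CD": 0.269},
  "age_targets": {
    "UC": {
      "male": {"mean": 53.8, "sd": 14.2},
      "female": {"mean": 58.6, "sd": 19.0}
    },
    "CD": {
      "male": {"mean": 52.3, "sd": 15.2},
      "female": {"mean": 52.8, "sd": 16.4}
    }
  },
  "age_bounds": [18, 74],
  "severity_proportions": {"mild_moderate": 0.7, "moderate_severe": 0.3},
  "initial_diagnosed_fraction": 0.7,
  "initial_biologic_fraction": 0.15
}
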