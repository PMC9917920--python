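{
  "region": "Hokkaido-synthetic",
  "base_weekly_new_patients": 12.0,
  "annual_growth": 1.06,
  "base_total_patients": 7000.0,
  "visit_interval": 11.0,
  "procedure_interval": 48.0,
  "biologic_interval": 8.0,
  "biologic_share": 0.12,
  "dispersion": 10.0,
  "start_date": "2015-01-05",
  "disruption": {
    "onset_week": 269,
    "depth": {
      "new_patients": 0.45,
      "outpatient_visits": 0.4,
      "procedures": 0.45,
      "biologics": 0.3
    },
    "duration_weeks": 12,
    "recovery_weeks": 24,
    "second_wave_start": 288,
    "second_wave_ratio": 0.4,
    "biologic_rise": 0.15,
    "biologic_rise_weeks": 5
  }
}
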