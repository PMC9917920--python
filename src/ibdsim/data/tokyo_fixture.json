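{
  "region": "Tokyo-synthetic",
  "base_weekly_new_patients": 60.0,
  "annual_growth": 1.09,
  "base_total_patients": 30000.0,
  "visit_interval": 10.0,
  "procedure_interval": 44.0,
  "biologic_interval": 8.0,
  "biologic_share": 0.15,
  "dispersion": 10.0,
  "start_date": "2015-01-05",
  "disruption": {
    "onset_week": 269,
    "depth": {
      "new_patients": 0.5,
      "outpatient_visits": 0.45,
      "procedures": 0.5,
      "biologics": 0.2
    },
    "duration_weeks": 8,
    "recovery_weeks": 12,
    "second_wave_start": 284,
    "second_wave_ratio": 0.4
  }
}
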