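{
  "task": "suite",
  "replicates": 5,
  "horizon": 104,
  "start_date": "2020-11-02",
  "capacity_headroom": 1.5,
  "regions": [
    {"name": "Tokyo", "population_config": "tokyo", "n_agents": 2000},
    {"name": "Hokkaido", "population_config": "hokkaido", "n_agents": 2000}
  ],
  "scenarios": [
    {
      "name": "pandemic",
      "type": "pandemic",
      "waves": {
        "peaks": [[10, 3000, 4], [40, 6000, 5], [80, 9000, 6]],
        "emergency_windows": [[8, 16]]
      },
      "response": {
        "case_saturation": 200.0,
        "max_demand_impact": 0.4,
        "max_supply_impact": 0.3,
        "emergency_boost": 0.15,
        "adaptation_halflife": 40.0
      }
    },
    {
      "name": "earthquake",
      "type": "earthquake",
      "params": {"start_week": 8, "severity": 0.8, "recovery_weeks": 12}
    },
    {
      "name": "financial_crisis",
      "type": "financial_crisis",
      "params": {"start_week": 8, "depth": 0.3, "duration_weeks": 52, "recovery_weeks": 26}
    }
  ]
}
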