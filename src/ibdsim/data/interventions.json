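{
  "physician outreach": {
    "description": "Physicians message their own patients at practice level (individual outreach to patients at risk)",
    "supply_impact": null,
    "demand_impact": 0.15,
    "supply_targets": [],
    "demand_targets": ["care_seeking", "continuous_care_visits", "biologic_refill"]
  },
  "system social signaling": {
    "description": "Hospital systems reinforce confidence locally (targeted social media and local press, small-footprint audience)",
    "supply_impact": null,
    "demand_impact": 0.40,
    "supply_targets": [],
    "demand_targets": ["care_seeking", "continuous_care_visits", "biologic_refill"]
  },
  "national confidence building": {
    "description": "Government messaging at societal level building confidence to stay engaged with care (broad-scale media, high-level official communication)",
    "supply_impact": null,
    "demand_impact": 0.60,
    "supply_targets": [],
    "demand_targets": ["care_seeking", "continuous_care_visits", "biologic_refill"]
  },
  "simple navigation assistance": {
    "description": "Education-focused initiatives on navigating care post-disruption (scheduling, where to go, who to see)",
    "supply_impact": 0.05,
    "demand_impact": 0.15,
    "supply_targets": ["outpatient_visits", "procedures", "biologic_dispensing"],
    "demand_targets": ["care_seeking", "continuous_care_visits", "biologic_refill"]
  },
  "barrier elimination": {
    "description": "Partnership with government and/or private sector to subsidize transportation when regular channels are unavailable",
    "supply_impact": 0.40,
    "demand_impact": 0.40,
    "supply_targets": ["outpatient_visits", "procedures", "biologic_dispensing"],
    "demand_targets": ["care_seeking", "continuous_care_visits", "biologic_refill"]
  },
  "emergency response infrastructure": {
    "description": "Infrastructure to provide emergency care on demand when the normal care setting is disrupted",
    "supply_impact": 0.60,
    "demand_impact": 0.55,
    "supply_targets": ["outpatient_visits", "procedures", "biologic_dispensing"],
    "demand_targets": ["care_seeking", "continuous_care_visits", "biologic_refill"]
  }
}
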