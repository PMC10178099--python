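{
  "metals": ["Hg", "Cd", "As", "Pb", "Cr"],
  "limit_mg_per_kg": {
    "Hg": 0.02,
    "Cd": 0.1,
    "As": 0.5,
    "Pb": 0.2,
    "Cr": 1.0
  },
  "rfd_mg_per_kg_day": {
    "Hg": 0.0001,
    "Cd": 0.001,
    "As": 0.0003,
    "Pb": 0.0037,
    "Cr": 0.003
  },
  "csf_kg_day_per_mg": {
    "Cd": 6.3,
    "As": 1.5,
    "Pb": 0.0085,
    "Cr": 0.5
  },
  "ef_days_per_year": 365.0,
  "ed_years": 70.0,
  "body_weight_kg": 60.0,
  "atc_years": 70.0
}
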