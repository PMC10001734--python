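{
  "criteria":             {"sum": 71.5578,  "n": 8, "theta": 1.118},
  "er_facilities":        {"sum": 24.5915,  "n": 5, "theta": 0.984},
  "healthcare_equipment": {"sum": 48.5833,  "n": 3, "theta": 5.398},
  "procedures_protocols": {"sum": 84.2253,  "n": 3, "theta": 9.358},
  "assisting_processes":  {"sum": 36.4767,  "n": 7, "theta": 0.744},
  "human_talent":         {"sum": 65.9084,  "n": 4, "theta": 4.119},
  "supply_medicines":     {"sum": 45.3754,  "n": 4, "theta": 2.836},
  "quality_healthcare":   {"sum": 120.7755, "n": 5, "theta": 4.831},
  "patient_safety":       {"sum": 30.7014,  "n": 4, "theta": 1.919}
}
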