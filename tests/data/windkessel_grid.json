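{
  "comment": "Physiological parameter ranges for the Windkessel grid checks",
  "R_mmHg_s_per_mL": {"min": 0.5, "max": 2.0, "n": 5},
  "C_mL_per_mmHg": {"min": 1.0, "max": 3.0, "n": 5},
  "SV_mL": {"min": 40.0, "max": 100.0, "n": 5},
  "F_bpm": {"min": 50.0, "max": 130.0, "n": 4}
}
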