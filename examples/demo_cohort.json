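{
  "seed": 1,
  "week_start": "2026-01-05",
  "heterogeneity": {"heat_coefficient": [0.00414, 0.00965]},
  "participants": [
    {"id": "P01", "dose_days": [1, 3, 4, 5, 7]},
    {"id": "P02", "dose_days": [1, 2, 4, 6, 7]},
    {"id": "P03", "dose_days": [1, 2, 3, 5, 6, 7]}
  ]
}
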