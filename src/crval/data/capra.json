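{
  "version": "default-1",
  "age_cutoff": 50,
  "age_points_ge_cutoff": 1,
  "psa_bands": [
    {"upper": 6.0, "points": 0},
    {"upper": 10.0, "points": 1},
    {"upper": 20.0, "points": 2},
    {"upper": 30.0, "points": 3},
    {"upper": null, "points": 4}
  ],
  "gleason_primary_45_points": 3,
  "gleason_secondary_45_points": 1,
  "stage_high_bands": ["T3", "T4"],
  "stage_high_points": 1,
  "ppc_cutoff": 0.34,
  "ppc_high_points": 1
}
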