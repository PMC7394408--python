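{
  "name": "penetration",
  "description": "Per-inclusion antibody penetration distances",
  "columns": [
    {"name": "inclusion_id", "dtype": "any"},
    {"name": "ratio", "dtype": "float"},
    {"name": "external_mean_distance", "dtype": "float"},
    {"name": "internal_mean_distance", "dtype": "float"},
    {"name": "penetration_px", "dtype": "float"}
  ]
}
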