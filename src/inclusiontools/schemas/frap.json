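{
  "name": "frap",
  "description": "Per-inclusion FRAP relative recovery",
  "columns": [
    {"name": "inclusion_id", "dtype": "any"},
    {"name": "time_min", "dtype": "float"},
    {"name": "relative_recovery", "dtype": "float"}
  ]
}
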