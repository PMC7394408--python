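{
  "name": "stall",
  "description": "Per-construct stall-reporter ratio summary",
  "columns": [
    {"name": "construct", "dtype": "str"},
    {"name": "n", "dtype": "int"},
    {"name": "n_excluded", "dtype": "int"},
    {"name": "median", "dtype": "float"},
    {"name": "q25", "dtype": "float"},
    {"name": "q75", "dtype": "float"}
  ]
}
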