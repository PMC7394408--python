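{
  "name": "maturity",
  "description": "Per-inclusion maturity classification",
  "columns": [
    {"name": "inclusion_id", "dtype": "any"},
    {"name": "flash_mean", "dtype": "float"},
    {"name": "cerulean_mean", "dtype": "float"},
    {"name": "ratio", "dtype": "float"},
    {"name": "population_mean", "dtype": "float"},
    {"name": "population_sem", "dtype": "float"},
    {"name": "label", "dtype": "str"}
  ]
}
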