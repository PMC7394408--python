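{
  "name": "events",
  "description": "Per-cell cytometry event table",
  "columns": [
    {"name": "event_id", "dtype": "int"},
    {"name": "construct", "dtype": "str"},
    {"name": "cerulean_area", "dtype": "float"},
    {"name": "cerulean_height", "dtype": "float"},
    {"name": "cerulean_width", "dtype": "float"},
    {"name": "tmr_area", "dtype": "float"},
    {"name": "gfp_area", "dtype": "float"},
    {"name": "mcherry_area", "dtype": "float"},
    {"name": "true_inclusion", "dtype": "bool"}
  ]
}
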