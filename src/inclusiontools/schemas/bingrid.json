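{
  "name": "bingrid",
  "description": "Tidy 20x4 inclusion-fraction surface",
  "columns": [
    {"name": "construct", "dtype": "str"},
    {"name": "cerulean_bin_lo", "dtype": "float"},
    {"name": "cerulean_bin_hi", "dtype": "float"},
    {"name": "tmr_category", "dtype": "str"},
    {"name": "n", "dtype": "int"},
    {"name": "n_inclusion", "dtype": "int"},
    {"name": "fraction", "dtype": "float"}
  ]
}
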