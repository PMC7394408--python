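{
  "name": "zones",
  "description": "Per-inclusion long-format zone intensities",
  "columns": [
    {"name": "inclusion_id", "dtype": "any"},
    {"name": "channel", "dtype": "str"},
    {"name": "zone", "dtype": "str"},
    {"name": "mean_intensity", "dtype": "float"},
    {"name": "ratio", "dtype": "float"},
    {"name": "label", "dtype": "str"}
  ]
}
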