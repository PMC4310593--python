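{
  "type": "object",
  "required": ["l_um", "L_um", "delta_L_um", "delta_L_norm", "parameters", "seed"],
  "properties": {
    "l_um": {"type": "number"},
    "L_um": {"type": "number"},
    "delta_L_um": {"type": "number"},
    "delta_L_norm": {"type": "number"},
    "parameters": {"type": "object"},
    "seed": {"type": ["integer", "null"]},
    "thickness_um": {"type": ["number", "null"]},
    "nuclear_density_per_100um2": {"type": ["number", "null"]}
  }
}
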