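{
  "type": "object",
  "required": ["px_lateral_um", "px_axial_um"],
  "properties": {
    "px_lateral_um": {"type": "number"},
    "px_axial_um": {"type": "number"},
    "ground_truth": {
      "type": "object",
      "properties": {
        "true_delta_linearity": {"type": ["number", "null"]},
        "true_nucleus_centers": {"type": "array", "items": {"type": "array"}},
        "boundary_model": {
          "type": "object",
          "required": ["baseline_depth"],
          "properties": {
            "baseline_depth": {"type": "number"},
            "sine_amplitude": {"type": "number"},
            "sine_period": {"type": "number"},
            "bumps": {"type": "array"},
            "roughness_sd": {"type": "number"}
          }
        },
        "true_surface_depth": {"type": "array", "items": {"type": "number"}},
        "true_thickness_profile": {"type": "array", "items": {"type": "number"}}
      }
    }
  }
}
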