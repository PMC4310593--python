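{
  "type": "object",
  "required": ["AUC", "cutoff", "sensitivity_pct", "specificity_pct", "rates", "anova"],
  "properties": {
    "AUC": {"type": "number"},
    "cutoff": {"type": "number"},
    "sensitivity_pct": {"type": "number"},
    "specificity_pct": {"type": "number"},
    "rates": {
      "type": "object",
      "required": ["TP", "FP", "TN", "FN"],
      "properties": {
        "TP": {"type": "number"},
        "FP": {"type": "number"},
        "TN": {"type": "number"},
        "FN": {"type": "number"}
      }
    },
    "anova": {
      "type": "object",
      "required": ["F", "p"],
      "properties": {"F": {"type": "number"}, "p": {"type": "number"}}
    },
    "seed": {"type": ["integer", "null"]}
  }
}
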