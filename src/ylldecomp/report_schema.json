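{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "YLL decomposition report",
  "type": "object",
  "required": [
    "labels", "yll0", "yll1", "delta_yll",
    "partial", "total", "residue_free", "percent", "warnings"
  ],
  "properties": {
    "labels": {
      "type": "object",
      "required": ["baseline", "comparison"],
      "properties": {
        "baseline": {"type": "string"},
        "comparison": {"type": "string"}
      }
    },
    "yll0": {"type": "number"},
    "yll1": {"type": "number"},
    "delta_yll": {"type": "number"},
    "partial": {"$ref": "#/$defs/approach"},
    "total": {"$ref": "#/$defs/approach"},
    "residue_free": {
      "type": "object",
      "required": ["age_structure", "death_rate", "age_at_death"],
      "properties": {
        "age_structure": {"type": "number"},
        "death_rate": {"type": "number"},
        "age_at_death": {"type": "number"}
      }
    },
    "percent": {"type": ["array", "null"], "items": {"type": "number"}},
    "percent_rounded": {"type": ["array", "null"], "items": {"type": "number"}},
    "warnings": {"type": "array", "items": {"type": "string"}}
  },
  "$defs": {
    "approach": {
      "type": "object",
      "required": [
        "approach", "age_structure", "death",
        "age_at_death", "death_rate", "residual"
      ],
      "properties": {
        "approach": {"type": "string"},
        "age_structure": {"type": "number"},
        "death": {"type": "number"},
        "age_at_death": {"type": "number"},
        "death_rate": {"type": "number"},
        "residual": {"type": "number"}
      }
    }
  }
}
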