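{
  "type": "object",
  "required": ["schema_version", "seed", "design", "scenarios"],
  "properties": {
    "schema_version": {"type": "integer"},
    "seed": {"type": "integer"},
    "design": {
      "type": "object",
      "required": ["length", "coverage", "woc_space", "search_bounds"],
      "properties": {
        "length": {"type": "number"},
        "coverage": {"type": "number"},
        "woc_space": {"type": "string"},
        "search_bounds": {"type": "array", "items": {"type": "integer"}}
      }
    },
    "elicitation": {
      "type": ["object", "null"],
      "properties": {
        "summary": {
          "type": "object",
          "required": ["mean", "variance", "n_experts"],
          "properties": {
            "mean": {"type": "number"},
            "variance": {"type": "number"},
            "n_experts": {"type": "integer"}
          }
        },
        "quantiles": {
          "type": "object",
          "required": ["levels", "values"],
          "properties": {
            "levels": {"type": "array", "items": {"type": "number"}},
            "values": {"type": "array", "items": {"type": "number"}},
            "domain": {"type": "array", "items": {"type": "number"}}
          }
        },
        "delta_star": {"type": "number"}
      }
    },
    "frequentist_n": {"type": ["integer", "null"]},
    "scenarios": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["prior", "criteria"],
        "properties": {
          "prior": {"type": "object"},
          "ess": {"type": ["number", "null"]},
          "criteria": {
            "type": "object",
            "additionalProperties": {"type": "object"}
          }
        }
      }
    }
  }
}
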