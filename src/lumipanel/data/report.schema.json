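{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "lumipanel call report",
  "type": "object",
  "required": ["schema_version", "samples"],
  "properties": {
    "schema_version": {"type": "string"},
    "samples": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["final_call", "specificities", "hla_positive", "negative", "flags", "beads"],
        "properties": {
          "final_call": {"type": "string"},
          "specificities": {"type": "array", "items": {"type": "string"}},
          "hla_positive": {"type": "boolean"},
          "negative": {"type": "boolean"},
          "flags": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["kind"],
              "properties": {
                "kind": {"type": "string"},
                "detail": {"type": "array", "items": {"type": "string"}}
              }
            }
          },
          "beads": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "required": ["reactive", "nonreactive", "borderline", "candidate_sets"],
              "properties": {
                "reactive": {"type": "array", "items": {"type": "string"}},
                "nonreactive": {"type": "array", "items": {"type": "string"}},
                "borderline": {"type": "array", "items": {"type": "string"}},
                "unexplained": {"type": "boolean"},
                "borderline_only": {"type": "boolean"},
                "candidate_sets": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["specificities", "cardinality", "prior_score", "rank"],
                    "properties": {
                      "specificities": {"type": "array", "items": {"type": "string"}},
                      "cardinality": {"type": "integer"},
                      "prior_score": {"type": "number"},
                      "rank": {"type": "integer"}
                    }
                  }
                }
              }
            }
          }
        }
      }
    },
    "structural_limitations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["specificity", "reason"],
        "properties": {
          "specificity": {"type": "string"},
          "reason": {"type": "string"}
        }
      }
    },
    "cutoffs": {"type": "object", "additionalProperties": {"type": "number"}},
    "concordance": {
      "type": "object",
      "required": ["n_compared", "n_agree", "percent_agreement"],
      "properties": {
        "n_compared": {"type": "integer"},
        "n_agree": {"type": "integer"},
        "percent_agreement": {"type": "number"},
        "discordant": {"type": "array"},
        "missing_reference": {"type": "array", "items": {"type": "string"}}
      }
    }
  }
}
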