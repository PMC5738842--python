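{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.invalid/retroharm/spec.schema.json",
  "title": "Harmonisation spec",
  "description": "Recipe for one harmonised variable: target categories plus, per study-wave, a category map, a threshold-bin rule, or a reasoned exclusion. The package validator (retroharm.rules.parse_spec) enforces this contract plus dictionary-dependent semantic checks that a schema cannot express.",
  "type": "object",
  "required": ["name", "target_categories", "rules"],
  "additionalProperties": false,
  "properties": {
    "name": {"type": "string", "minLength": 1},
    "description": {"type": "string"},
    "variable_group": {"type": "string", "minLength": 1},
    "target_categories": {
      "type": "array",
      "items": {"type": "string", "minLength": 1},
      "contains": {"const": "Missing"},
      "uniqueItems": true,
      "minItems": 2
    },
    "rules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["study_id", "wave", "kind"],
        "properties": {
          "study_id": {"type": "string", "minLength": 1},
          "wave": {"type": "integer", "minimum": 1},
          "kind": {"enum": ["category_map", "threshold_bin", "exclusion"]},
          "source_variable": {"type": "string"},
          "mapping": {
            "type": "object",
            "additionalProperties": {"type": "string"}
          },
          "unmapped_policy": {"enum": ["error", "missing"]},
          "multi_select_priority": {
            "type": "array",
            "items": {"type": "string"}
          },
          "bins": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["label"],
              "properties": {
                "lower": {"type": "number"},
                "upper": {"type": "number"},
                "label": {"type": "string"},
                "lower_inclusive": {"type": "boolean"},
                "upper_inclusive": {"type": "boolean"}
              }
            }
          },
          "mode_gate": {
            "type": "object",
            "required": ["mode_variable", "sources"],
            "properties": {
              "mode_variable": {"type": "string"},
              "sources": {
                "type": "object",
                "additionalProperties": {
                  "oneOf": [
                    {"type": "string"},
                    {
                      "type": "object",
                      "required": ["hours", "minutes"],
                      "properties": {
                        "hours": {"type": "string"},
                        "minutes": {"type": "string"}
                      }
                    }
                  ]
                }
              }
            }
          },
          "source_preference": {
            "type": "object",
            "required": ["selectors"],
            "properties": {
              "selectors": {
                "type": "array",
                "minItems": 1,
                "items": {
                  "type": "object",
                  "properties": {
                    "variable": {"type": "string"},
                    "respondent": {
                      "enum": ["child", "parent", "teacher", "objective", "unknown"]
                    }
                  }
                }
              },
              "conflict_policy": {"enum": ["prefer_first", "missing_if_conflict"]}
            }
          },
          "inference": {
            "type": "object",
            "required": ["variables", "inferred_category"],
            "properties": {
              "variables": {"type": "array", "items": {"type": "string"}, "minItems": 1},
              "inferred_category": {"type": "string"},
              "negative_values": {"type": "array", "items": {"type": "string"}}
            }
          },
          "reason": {"type": "string", "minLength": 1}
        },
        "allOf": [
          {
            "if": {"properties": {"kind": {"const": "exclusion"}}},
            "then": {"required": ["reason"]}
          },
          {
            "if": {"properties": {"kind": {"const": "category_map"}}},
            "then": {"required": ["mapping"]}
          },
          {
            "if": {"properties": {"kind": {"const": "threshold_bin"}}},
            "then": {"required": ["bins"]}
          }
        ]
      }
    }
  }
}
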