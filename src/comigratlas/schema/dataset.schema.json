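{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "comigratlas dataset export",
  "type": "object",
  "required": ["schema_version", "constants_version", "parameters", "n_entries", "entries"],
  "properties": {
    "schema_version": {"type": "string"},
    "constants_version": {"type": "string"},
    "parameters": {"type": "object"},
    "n_entries": {"type": "integer", "minimum": 1},
    "entries": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "accession", "description", "profile", "peaks",
          "partners_by_slice", "similar_proteins", "total_empai",
          "n_slices_detected"
        ],
        "properties": {
          "accession": {"type": "string", "minLength": 1},
          "description": {"type": "string"},
          "profile": {"type": "array", "items": {"type": "number", "minimum": 0}},
          "peaks": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["apex_slice", "left_slice", "right_slice", "apex_value"],
              "properties": {
                "apex_slice": {"type": "integer", "minimum": 1},
                "left_slice": {"type": "integer", "minimum": 1},
                "right_slice": {"type": "integer", "minimum": 1},
                "apex_value": {"type": "number", "exclusiveMinimum": 0},
                "est_mass_kda": {"type": ["number", "null"]},
                "extrapolated": {"type": ["boolean", "null"]}
              }
            }
          },
          "partners_by_slice": {
            "type": "object",
            "additionalProperties": {"type": "array", "items": {"type": "string"}}
          },
          "similar_proteins": {
            "type": "array",
            "items": {
              "type": "array",
              "prefixItems": [{"type": "string"}, {"type": "number"}]
            }
          },
          "total_empai": {"type": "number", "minimum": 0},
          "n_slices_detected": {"type": "integer", "minimum": 0}
        }
      }
    }
  }
}
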