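{
  "$comment": "Repo-local schema for the FHIR-style FamilyMemberHistory output. One object per family chain; conditions carry concept codes and the negated/nonnegated certainty attribute.",
  "type": "object",
  "required": ["resourceType", "patient", "relationship", "condition"],
  "properties": {
    "resourceType": {"type": "string", "enum": ["FamilyMemberHistory"]},
    "patient": {
      "type": "object",
      "required": ["reference"],
      "properties": {"reference": {"type": "string"}}
    },
    "relationship": {
      "type": "object",
      "required": ["text", "side"],
      "properties": {
        "text": {"type": "string"},
        "side": {"type": "string", "enum": ["Maternal", "Paternal", "NA"]}
      }
    },
    "deceased": {"type": "boolean"},
    "age": {"type": "array", "items": {"type": "integer"}},
    "condition": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code", "certainty"],
        "properties": {
          "code": {
            "type": "object",
            "required": ["text"],
            "properties": {
              "cui": {"type": "string"},
              "snomed": {"type": "string"},
              "text": {"type": "string"}
            }
          },
          "certainty": {"type": "string", "enum": ["negated", "nonnegated"]},
          "kind": {"type": "string", "enum": ["observation", "living_status"]}
        }
      }
    }
  }
}
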