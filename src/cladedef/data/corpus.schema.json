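{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/cladedef/corpus.schema.json",
  "title": "cladedef definition corpus",
  "description": "A corpus of rank-free phylogenetic clade definitions. Each entry mirrors the CladeDefinition structure plus the raw abbreviated-notation string, which must re-parse to the structured fields.",
  "type": "object",
  "required": ["version", "entries"],
  "properties": {
    "version": {"type": "string"},
    "alias_map": {
      "type": "object",
      "description": "Alternate tip label -> accepted specifier name",
      "additionalProperties": {"type": "string"}
    },
    "entries": {
      "type": "array",
      "items": {"$ref": "#/definitions/entry"}
    }
  },
  "definitions": {
    "connective": {"enum": ["and", "or", "none"]},
    "entry": {
      "type": "object",
      "required": [
        "clade_name", "status", "registration_number", "kind", "abbreviated",
        "internal", "external", "external_connective",
        "qualifying_excluded", "qualifying_connective", "context"
      ],
      "properties": {
        "clade_name": {"type": "string", "minLength": 1},
        "authorship": {"type": "string"},
        "status": {"enum": ["converted", "new"]},
        "registration_number": {"type": "integer", "exclusiveMinimum": 0},
        "kind": {"enum": ["minimum", "maximum"]},
        "abbreviated": {"type": "string", "minLength": 1},
        "internal": {"type": "array", "items": {"type": "string"}, "minItems": 1},
        "external": {"type": "array", "items": {"type": "string"}},
        "external_connective": {"$ref": "#/definitions/connective"},
        "qualifying_excluded": {"type": "array", "items": {"type": "string"}},
        "qualifying_connective": {"$ref": "#/definitions/connective"},
        "context": {
          "oneOf": [
            {"type": "null"},
            {
              "type": "object",
              "required": ["polarity", "contexts", "connective"],
              "properties": {
                "polarity": {"enum": ["within", "outside"]},
                "contexts": {"type": "array", "items": {"type": "string"}, "minItems": 1},
                "connective": {"$ref": "#/definitions/connective"}
              }
            }
          ]
        }
      }
    }
  }
}
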