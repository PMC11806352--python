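{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rna2d interchange document",
  "description": "Frozen dialect of the RNA 2D JSON document written and read by rna2d.document. Residues carry 1-based display indices; basePairs and labels reference residues by 0-based position within their molecule. Validation is performed structurally by rna2d.document.validate_document_dict; this file is the normative description of the field vocabulary.",
  "type": "object",
  "required": ["rnaComplexes"],
  "properties": {
    "rnaComplexes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "rnaMolecules"],
        "properties": {
          "name": {"type": "string"},
          "rnaMolecules": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["name", "sequence", "basePairs", "labels"],
              "properties": {
                "name": {"type": "string"},
                "sequence": {
                  "type": "array",
                  "minItems": 1,
                  "items": {
                    "type": "object",
                    "required": ["residueName", "residueIndex", "x", "y"],
                    "properties": {
                      "residueName": {"type": "string", "minLength": 1, "maxLength": 1},
                      "residueIndex": {"type": "integer", "minimum": 1},
                      "x": {"type": "number"},
                      "y": {"type": "number"},
                      "classes": {"type": "array", "items": {"type": "string"}}
                    }
                  }
                },
                "basePairs": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["residueIndex1", "residueIndex2", "lw"],
                    "properties": {
                      "residueIndex1": {"type": "integer", "minimum": 0},
                      "residueIndex2": {"type": "integer", "minimum": 0},
                      "lw": {
                        "type": "string",
                        "pattern": "^(canonical|[ct][WHS][WHS])$"
                      },
                      "predicted": {"type": "boolean", "default": false}
                    }
                  }
                },
                "labels": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["residueIndex", "texts"],
                    "properties": {
                      "residueIndex": {"type": "integer", "minimum": 0},
                      "texts": {"type": "array", "items": {"type": "string"}}
                    }
                  }
                }
              }
            }
          }
        }
      }
    },
    "classes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "colour"],
        "properties": {
          "name": {"type": "string"},
          "colour": {"type": "string"},
          "fontSize": {"type": "number", "default": 8.0},
          "visibility": {"type": "string", "enum": ["visible", "hidden"], "default": "visible"}
        }
      }
    }
  }
}
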