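{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cobbkit spine annotation container",
  "type": "object",
  "required": ["annotations"],
  "properties": {
    "annotations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["subject_id", "vertebrae"],
        "properties": {
          "subject_id": {"type": "string"},
          "image_size": {
            "type": ["array", "null"],
            "items": {"type": "number"},
            "minItems": 2,
            "maxItems": 2
          },
          "pixel_spacing": {"type": ["number", "null"]},
          "vertebrae": {
            "type": "array",
            "minItems": 4,
            "items": {
              "type": "object",
              "required": ["label", "corners"],
              "properties": {
                "label": {"type": ["string", "integer"]},
                "corners": {
                  "type": "array",
                  "minItems": 4,
                  "maxItems": 4,
                  "items": {
                    "type": "array",
                    "minItems": 2,
                    "maxItems": 2,
                    "items": {"type": "number"}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
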