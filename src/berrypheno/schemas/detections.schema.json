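{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "berrypheno detection records",
  "type": "object",
  "required": ["instances"],
  "properties": {
    "instances": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["image", "polygon", "label"],
        "properties": {
          "image": {"type": "string"},
          "polygon": {
            "type": "array",
            "items": {"type": "array", "items": {"type": "number"}}
          },
          "label": {"type": "string", "enum": ["mature", "immature"]},
          "score": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    }
  }
}
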