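{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "berrypheno evaluation report",
  "type": "object",
  "required": ["thresholds", "map", "per_class_ap", "error_tally"],
  "properties": {
    "thresholds": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}},
    "map": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
    },
    "per_class_ap": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
      }
    },
    "mean_iou": {"type": "number", "minimum": 0, "maximum": 1},
    "primary_threshold": {"type": "number", "minimum": 0, "maximum": 1},
    "floor_threshold": {"type": "number", "minimum": 0, "maximum": 1},
    "error_tally": {
      "type": "object",
      "required": ["one_as_two", "missed", "two_as_one", "partial"],
      "additionalProperties": {"type": "integer", "minimum": 0}
    },
    "n_predictions": {"type": "integer", "minimum": 0},
    "n_ground_truth": {"type": "integer", "minimum": 0},
    "pr_curves": {"type": "object"}
  }
}
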