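{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pkeye run configuration",
  "type": "object",
  "properties": {
    "seed": {"type": "integer", "minimum": 0},
    "recording_rate_hz": {"type": "number", "exclusiveMinimum": 0, "maximum": 50},
    "controllers": {"type": "integer", "minimum": 1, "maximum": 6},
    "sensors_per_controller": {"type": "integer", "minimum": 1, "maximum": 6},
    "output_dir": {"type": "string"},
    "membrane": {"type": "object"},
    "network": {"type": "object"},
    "pk": {"type": "object"},
    "motion": {"type": "object"},
    "probe": {"type": "object"}
  },
  "additionalProperties": false
}
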