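{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "synthzoo-registry.schema.json",
  "title": "synthzoo model registry",
  "description": "A registry is a JSON object keyed by model ids (^\\d{5}(_[A-Z0-9]+)+$). Each value holds the three metadata sections. Schema version 1.0. Shipped for documentation and external tooling; synthzoo validates in code (registry.validate_metadata).",
  "type": "object",
  "propertyNames": {"pattern": "^\\d{5}(_[A-Z0-9]+)+$"},
  "additionalProperties": {
    "type": "object",
    "required": ["execution", "selection", "description"],
    "properties": {
      "execution": {
        "type": "object",
        "required": ["package_location", "package_name", "generate_method_name", "image_size"],
        "properties": {
          "package_location": {"type": "string", "description": "local path or URI of the package directory / ZIP"},
          "package_name": {"type": "string"},
          "weights_name": {"type": "string", "description": "weights file stem; empty for weight-free models"},
          "weights_extension": {"type": "string", "description": "e.g. .pt; empty when weights_name is empty"},
          "dependencies": {"type": "array", "items": {"type": "string", "minLength": 1}},
          "generate_method_name": {"type": "string", "minLength": 1},
          "generate_args": {"type": "object", "description": "default keyword arguments of the generate callable"},
          "image_size": {"type": "array", "items": {"type": "integer", "minimum": 0}, "minItems": 3, "maxItems": 3, "description": "(height, width, channels)"},
          "latent_dim": {"type": "integer", "minimum": 1, "description": "optional: latent input size for noise-to-image models"},
          "value_range": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2, "description": "optional: declared output pixel range, default [0, 255]"}
        }
      },
      "selection": {
        "type": "object",
        "properties": {
          "performance": {"type": "object", "description": "nested metric map, e.g. {\"FID\": 80.51}; all numbers finite"},
          "keywords": {"type": "array", "items": {"type": "string", "minLength": 1}}
        }
      },
      "description": {
        "type": "object",
        "required": ["title"],
        "properties": {
          "title": {"type": "string", "minLength": 1},
          "modality": {"type": "string"},
          "output_type": {"type": "string"},
          "training_dataset": {"type": "string"},
          "license": {"type": "string"},
          "date": {"type": "string", "description": "ISO-8601"},
          "publication": {"type": "string"}
        }
      }
    }
  }
}
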