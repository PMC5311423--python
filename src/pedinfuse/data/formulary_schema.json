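{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pedinfuse formulary",
  "type": "object",
  "required": ["drugs"],
  "properties": {
    "drugs": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "mode", "vial_volume_ml"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "mode": {"enum": ["continuous", "bolus"]},
          "stock_concentration_ug_per_ml": {"type": "number", "exclusiveMinimum": 0},
          "stock_concentration_mg_per_ml": {"type": "number", "exclusiveMinimum": 0},
          "vial_volume_ml": {"type": "number", "exclusiveMinimum": 0},
          "vial_mass_ug": {"type": "number", "exclusiveMinimum": 0},
          "vial_mass_mg": {"type": "number", "exclusiveMinimum": 0},
          "dose_rate_min": {"type": "number", "minimum": 0},
          "dose_rate_max": {"type": "number", "minimum": 0},
          "bolus_dose_mg_per_kg": {"type": "number", "exclusiveMinimum": 0},
          "shann_scale": {"type": "number", "exclusiveMinimum": 0}
        },
        "oneOf": [
          {
            "properties": {"mode": {"const": "continuous"}},
            "required": ["dose_rate_min", "dose_rate_max"],
            "not": {"required": ["bolus_dose_mg_per_kg"]}
          },
          {
            "properties": {"mode": {"const": "bolus"}},
            "required": ["bolus_dose_mg_per_kg"],
            "not": {"anyOf": [{"required": ["dose_rate_min"]}, {"required": ["shann_scale"]}]}
          }
        ]
      }
    }
  }
}
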