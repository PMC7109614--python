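{
  "description": "One forced expiratory maneuver.\n\nCurve-shape acceptability flags (slow start, glottis closure, variable\neffort) are operator judgements entered at the bedside; only\n``early_termination`` can also be derived, from the forced expiratory\ntime when the device reports it.",
  "properties": {
    "fvc_l": {
      "description": "forced vital capacity, liters",
      "exclusiveMaximum": 10.0,
      "exclusiveMinimum": 0.2,
      "title": "Fvc L",
      "type": "number"
    },
    "fev1_l": {
      "description": "FEV1, liters",
      "exclusiveMinimum": 0.0,
      "title": "Fev1 L",
      "type": "number"
    },
    "fet_s": {
      "anyOf": [
        {
          "exclusiveMinimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "description": "forced expiratory time, s",
      "title": "Fet S"
    },
    "slow_start": {
      "default": false,
      "title": "Slow Start",
      "type": "boolean"
    },
    "early_termination": {
      "default": false,
      "title": "Early Termination",
      "type": "boolean"
    },
    "glottis_closure": {
      "default": false,
      "title": "Glottis Closure",
      "type": "boolean"
    },
    "variable_effort": {
      "default": false,
      "title": "Variable Effort",
      "type": "boolean"
    }
  },
  "required": [
    "fvc_l",
    "fev1_l"
  ],
  "title": "SpirometryAttempt",
  "type": "object"
}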