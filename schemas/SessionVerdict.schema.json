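{
  "description": "Derived interpretation of a session (produced, never hand-entered).",
  "properties": {
    "session_id": {
      "title": "Session Id",
      "type": "string"
    },
    "calibrated": {
      "title": "Calibrated",
      "type": "boolean"
    },
    "acceptable_attempts": {
      "title": "Acceptable Attempts",
      "type": "integer"
    },
    "reproducible": {
      "title": "Reproducible",
      "type": "boolean"
    },
    "reason": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Reason"
    },
    "delta_fvc_l": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Delta Fvc L"
    },
    "delta_fev1_l": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Delta Fev1 L"
    },
    "valid": {
      "title": "Valid",
      "type": "boolean"
    },
    "best_fvc_l": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Best Fvc L"
    },
    "best_fev1_l": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Best Fev1 L"
    },
    "ratio": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Ratio"
    },
    "threshold_mode": {
      "anyOf": [
        {
          "enum": [
            "fixed",
            "lln"
          ],
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Threshold Mode"
    },
    "threshold_used": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Threshold Used"
    },
    "obstruction": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Obstruction"
    }
  },
  "required": [
    "session_id",
    "calibrated",
    "acceptable_attempts",
    "reproducible",
    "valid"
  ],
  "title": "SessionVerdict",
  "type": "object"
}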