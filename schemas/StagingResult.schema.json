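{
  "$defs": {
    "ReferralReport": {
      "description": "Structured report accompanying a specialist referral.",
      "properties": {
        "patient_id": {
          "title": "Patient Id",
          "type": "string"
        },
        "scores": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Scores",
          "type": "object"
        },
        "spirometry_summary": {
          "title": "Spirometry Summary",
          "type": "string"
        },
        "exacerbation_history": {
          "title": "Exacerbation History",
          "type": "string"
        },
        "comorbidity_notes": {
          "default": "",
          "title": "Comorbidity Notes",
          "type": "string"
        }
      },
      "required": [
        "patient_id",
        "scores",
        "spirometry_summary",
        "exacerbation_history"
      ],
      "title": "ReferralReport",
      "type": "object"
    }
  },
  "description": "Severity/impact staging outcome plus the referral decision.",
  "properties": {
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "bode": {
      "anyOf": [
        {
          "maximum": 10,
          "minimum": 0,
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Bode"
    },
    "bodex": {
      "maximum": 9,
      "minimum": 0,
      "title": "Bodex",
      "type": "integer"
    },
    "driving_index": {
      "enum": [
        "bode",
        "bodex",
        "fev1"
      ],
      "title": "Driving Index",
      "type": "string"
    },
    "severity": {
      "enum": [
        "mild",
        "moderate",
        "severe",
        "very severe"
      ],
      "title": "Severity",
      "type": "string"
    },
    "impact": {
      "enum": [
        "low",
        "moderate",
        "high",
        "very high"
      ],
      "title": "Impact",
      "type": "string"
    },
    "refer": {
      "title": "Refer",
      "type": "boolean"
    },
    "referral_reasons": {
      "items": {
        "type": "string"
      },
      "title": "Referral Reasons",
      "type": "array"
    },
    "report": {
      "anyOf": [
        {
          "$ref": "#/$defs/ReferralReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "patient_id",
    "bodex",
    "driving_index",
    "severity",
    "impact",
    "refer"
  ],
  "title": "StagingResult",
  "type": "object"
}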