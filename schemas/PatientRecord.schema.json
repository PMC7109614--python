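{
  "description": "Demographics, anthropometrics and history for one patient.",
  "properties": {
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "age": {
      "maximum": 130,
      "minimum": 0,
      "title": "Age",
      "type": "integer"
    },
    "sex": {
      "enum": [
        "male",
        "female"
      ],
      "title": "Sex",
      "type": "string"
    },
    "height_cm": {
      "exclusiveMinimum": 0,
      "title": "Height Cm",
      "type": "number"
    },
    "weight_kg": {
      "exclusiveMinimum": 0,
      "title": "Weight Kg",
      "type": "number"
    },
    "ethnic_group": {
      "default": "caucasian",
      "title": "Ethnic Group",
      "type": "string"
    },
    "smoking_status": {
      "default": "never",
      "enum": [
        "never",
        "ex",
        "current"
      ],
      "title": "Smoking Status",
      "type": "string"
    },
    "pack_years": {
      "default": 0.0,
      "minimum": 0,
      "title": "Pack Years",
      "type": "number"
    },
    "dyspnea": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Dyspnea"
    },
    "chronic_cough": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Chronic Cough"
    },
    "chronic_sputum": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Chronic Sputum"
    },
    "recurrent_infections": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Recurrent Infections"
    },
    "risk_factor_exposure": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Risk Factor Exposure"
    },
    "family_history_copd": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Family History Copd"
    }
  },
  "required": [
    "patient_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg"
  ],
  "title": "PatientRecord",
  "type": "object"
}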