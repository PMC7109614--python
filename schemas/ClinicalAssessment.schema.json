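{
  "description": "Inputs to severity and impact staging.",
  "properties": {
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "bmi": {
      "exclusiveMinimum": 0,
      "title": "Bmi",
      "type": "number"
    },
    "fev1_pct_pred": {
      "description": "FEV1 as % of predicted",
      "exclusiveMinimum": 0,
      "title": "Fev1 Pct Pred",
      "type": "number"
    },
    "mmrc": {
      "description": "mMRC dyspnea grade",
      "maximum": 4,
      "minimum": 0,
      "title": "Mmrc",
      "type": "integer"
    },
    "exacerbations_last_year": {
      "minimum": 0,
      "title": "Exacerbations Last Year",
      "type": "integer"
    },
    "hospitalizations_last_year": {
      "default": 0,
      "minimum": 0,
      "title": "Hospitalizations Last Year",
      "type": "integer"
    },
    "cat_score": {
      "description": "COPD Assessment Test total",
      "maximum": 40,
      "minimum": 0,
      "title": "Cat Score",
      "type": "integer"
    },
    "six_mwd_m": {
      "anyOf": [
        {
          "minimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "description": "6-minute walk distance, m",
      "title": "Six Mwd M"
    }
  },
  "required": [
    "patient_id",
    "bmi",
    "fev1_pct_pred",
    "mmrc",
    "exacerbations_last_year",
    "cat_score"
  ],
  "title": "ClinicalAssessment",
  "type": "object"
}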