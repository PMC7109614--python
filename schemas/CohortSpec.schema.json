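{
  "description": "Parameters of a synthetic cohort (all probabilities in [0, 1]).",
  "properties": {
    "n": {
      "minimum": 1,
      "title": "N",
      "type": "integer"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "age_min": {
      "default": 41,
      "title": "Age Min",
      "type": "integer"
    },
    "age_max": {
      "default": 85,
      "title": "Age Max",
      "type": "integer"
    },
    "female_fraction": {
      "default": 0.5,
      "maximum": 1,
      "minimum": 0,
      "title": "Female Fraction",
      "type": "number"
    },
    "smoking_prevalence": {
      "default": 0.6,
      "maximum": 1,
      "minimum": 0,
      "title": "Smoking Prevalence",
      "type": "number"
    },
    "obstruction_prevalence": {
      "default": 0.3,
      "maximum": 1,
      "minimum": 0,
      "title": "Obstruction Prevalence",
      "type": "number"
    },
    "obstructed_ratio_gap_mean": {
      "default": 0.08,
      "minimum": 0,
      "title": "Obstructed Ratio Gap Mean",
      "type": "number"
    },
    "obstructed_ratio_gap_sd": {
      "default": 0.04,
      "minimum": 0,
      "title": "Obstructed Ratio Gap Sd",
      "type": "number"
    },
    "normal_ratio_gap_mean": {
      "default": 0.07,
      "minimum": 0,
      "title": "Normal Ratio Gap Mean",
      "type": "number"
    },
    "normal_ratio_gap_sd": {
      "default": 0.03,
      "minimum": 0,
      "title": "Normal Ratio Gap Sd",
      "type": "number"
    },
    "attempt_noise_sd_l": {
      "default": 0.05,
      "description": "within-session noise sigma, L",
      "minimum": 0,
      "title": "Attempt Noise Sd L",
      "type": "number"
    },
    "screening_sensitivity": {
      "default": 0.9,
      "maximum": 1,
      "minimum": 0,
      "title": "Screening Sensitivity",
      "type": "number"
    },
    "screening_specificity": {
      "default": 0.85,
      "maximum": 1,
      "minimum": 0,
      "title": "Screening Specificity",
      "type": "number"
    },
    "no_show_probability": {
      "default": 0.1,
      "maximum": 1,
      "minimum": 0,
      "title": "No Show Probability",
      "type": "number"
    },
    "six_mwd_available_probability": {
      "default": 0.7,
      "maximum": 1,
      "minimum": 0,
      "title": "Six Mwd Available Probability",
      "type": "number"
    },
    "start_date": {
      "default": "2026-01-05T09:00:00",
      "format": "date-time",
      "title": "Start Date",
      "type": "string"
    },
    "group_weights": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Group Weights",
      "type": "object"
    }
  },
  "required": [
    "n"
  ],
  "title": "CohortSpec",
  "type": "object"
}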