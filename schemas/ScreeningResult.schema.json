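{
  "description": "Scored screening questionnaire.",
  "properties": {
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "answers": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Answers",
      "type": "object"
    },
    "total": {
      "title": "Total",
      "type": "integer"
    },
    "positive": {
      "title": "Positive",
      "type": "boolean"
    },
    "screening_date": {
      "format": "date",
      "title": "Screening Date",
      "type": "string"
    }
  },
  "required": [
    "patient_id",
    "answers",
    "total",
    "positive",
    "screening_date"
  ],
  "title": "ScreeningResult",
  "type": "object"
}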