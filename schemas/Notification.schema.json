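{
  "description": "An outbound message artifact (the engine never sends anything).",
  "properties": {
    "recipient_role": {
      "enum": [
        "patient",
        "doctor"
      ],
      "title": "Recipient Role",
      "type": "string"
    },
    "kind": {
      "enum": [
        "screening_invite",
        "screening_positive_alert",
        "appointment_reminder"
      ],
      "title": "Kind",
      "type": "string"
    },
    "scheduled_time": {
      "format": "date-time",
      "title": "Scheduled Time",
      "type": "string"
    },
    "payload_key": {
      "title": "Payload Key",
      "type": "string"
    },
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    }
  },
  "required": [
    "recipient_role",
    "kind",
    "scheduled_time",
    "payload_key",
    "patient_id"
  ],
  "title": "Notification",
  "type": "object"
}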