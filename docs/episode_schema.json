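{
  "$defs": {
    "AugmentationRecord": {
      "description": "Use of a non-antidepressant augmenting agent (e.g. lithium).",
      "properties": {
        "agent_name": {
          "title": "Agent Name",
          "type": "string"
        },
        "used": {
          "default": true,
          "title": "Used",
          "type": "boolean"
        },
        "duration_weeks": {
          "default": 0.0,
          "title": "Duration Weeks",
          "type": "number"
        }
      },
      "required": [
        "agent_name"
      ],
      "title": "AugmentationRecord",
      "type": "object"
    },
    "ECTCourse": {
      "description": "A course of electroconvulsive therapy.",
      "properties": {
        "n_sessions": {
          "title": "N Sessions",
          "type": "integer"
        },
        "completed": {
          "default": true,
          "title": "Completed",
          "type": "boolean"
        },
        "outcome": {
          "$ref": "#/$defs/Outcome",
          "default": "unknown"
        }
      },
      "required": [
        "n_sessions"
      ],
      "title": "ECTCourse",
      "type": "object"
    },
    "Instrument": {
      "description": "Symptom-severity rating instruments with built-in MSM threshold tables.",
      "enum": [
        "QIDS-C16",
        "QIDS-SR16",
        "IDS-C",
        "IDS-SR",
        "HRSD17",
        "MADRS",
        "CGI",
        "PSR",
        "ICD10-checklist"
      ],
      "title": "Instrument",
      "type": "string"
    },
    "Outcome": {
      "description": "End-of-trial clinical outcome of one treatment course.",
      "enum": [
        "remitted",
        "responded_not_remitted",
        "no_response",
        "unknown"
      ],
      "title": "Outcome",
      "type": "string"
    },
    "SeverityAssessment": {
      "description": "One instrument total score with a psychotic-features flag.\n\n``score`` is the instrument *total* (item-level scoring is out of scope);\nfor the ICD10 checklist it is the ordinal severity category 1-5 directly.",
      "properties": {
        "instrument": {
          "$ref": "#/$defs/Instrument"
        },
        "score": {
          "title": "Score",
          "type": "integer"
        },
        "psychotic_features": {
          "default": false,
          "title": "Psychotic Features",
          "type": "boolean"
        },
        "assessment_date": {
          "anyOf": [
            {
              "format": "date",
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Assessment Date"
        }
      },
      "required": [
        "instrument",
        "score"
      ],
      "title": "SeverityAssessment",
      "type": "object"
    },
    "TreatmentTrial": {
      "description": "One antidepressant course.\n\nDuration may be given explicitly in weeks, as start/end dates, or both;\nwhen both are present the dates are authoritative and a disagreement of\nmore than one week is flagged by :func:`validate_episode` (retrospective\ntreatment histories are often date-imprecise).\n\n``confirmatory_outcome`` is a second remission-status measure taken after\nthe end-of-trial one; it is only consulted under the sustained\n(two-months-in-remission) remission rule.",
      "properties": {
        "drug_name": {
          "title": "Drug Name",
          "type": "string"
        },
        "dose_mg_per_day": {
          "title": "Dose Mg Per Day",
          "type": "number"
        },
        "duration_weeks": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Duration Weeks"
        },
        "start_date": {
          "anyOf": [
            {
              "format": "date",
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Start Date"
        },
        "end_date": {
          "anyOf": [
            {
              "format": "date",
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "End Date"
        },
        "adherent": {
          "default": true,
          "title": "Adherent",
          "type": "boolean"
        },
        "tolerated": {
          "default": true,
          "title": "Tolerated",
          "type": "boolean"
        },
        "outcome": {
          "$ref": "#/$defs/Outcome",
          "default": "unknown"
        },
        "instrument_outcome": {
          "anyOf": [
            {
              "$ref": "#/$defs/SeverityAssessment"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "confirmatory_outcome": {
          "anyOf": [
            {
              "$ref": "#/$defs/SeverityAssessment"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "drug_name",
        "dose_mg_per_day"
      ],
      "title": "TreatmentTrial",
      "type": "object"
    }
  },
  "description": "One depressive episode: the MSM's unit of staging.\n\n``onset_date`` is the onset of the full episode for first episodes and\nthe onset of prodromal relapse symptoms for subsequent episodes.",
  "properties": {
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "onset_date": {
      "format": "date",
      "title": "Onset Date",
      "type": "string"
    },
    "assessment_date": {
      "format": "date",
      "title": "Assessment Date",
      "type": "string"
    },
    "baseline_severity": {
      "$ref": "#/$defs/SeverityAssessment"
    },
    "is_first_episode": {
      "default": true,
      "title": "Is First Episode",
      "type": "boolean"
    },
    "trials": {
      "default": [],
      "items": {
        "$ref": "#/$defs/TreatmentTrial"
      },
      "title": "Trials",
      "type": "array"
    },
    "augmentations": {
      "default": [],
      "items": {
        "$ref": "#/$defs/AugmentationRecord"
      },
      "title": "Augmentations",
      "type": "array"
    },
    "ect": {
      "anyOf": [
        {
          "$ref": "#/$defs/ECTCourse"
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
    "onset_date",
    "assessment_date",
    "baseline_severity"
  ],
  "title": "EpisodeRecord",
  "type": "object"
}
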