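{
  "$defs": {
    "StageResult": {
      "properties": {
        "status": {
          "title": "Status",
          "type": "string"
        },
        "detail": {
          "default": "",
          "title": "Detail",
          "type": "string"
        },
        "data": {
          "additionalProperties": true,
          "default": {},
          "title": "Data",
          "type": "object"
        }
      },
      "required": [
        "status"
      ],
      "title": "StageResult",
      "type": "object"
    }
  },
  "description": "Validated, JSON-serializable pipeline output.",
  "properties": {
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "blocks": {
      "items": {
        "type": "string"
      },
      "title": "Blocks",
      "type": "array"
    },
    "priming_bf": {
      "additionalProperties": {
        "$ref": "#/$defs/StageResult"
      },
      "default": {},
      "title": "Priming Bf",
      "type": "object"
    },
    "sensitivity_bf": {
      "additionalProperties": {
        "$ref": "#/$defs/StageResult"
      },
      "default": {},
      "title": "Sensitivity Bf",
      "type": "object"
    },
    "regression": {
      "additionalProperties": {
        "$ref": "#/$defs/StageResult"
      },
      "default": {},
      "title": "Regression",
      "type": "object"
    },
    "grt": {
      "additionalProperties": {
        "$ref": "#/$defs/StageResult"
      },
      "default": {},
      "title": "Grt",
      "type": "object"
    },
    "comparison": {
      "anyOf": [
        {
          "$ref": "#/$defs/StageResult"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "config_hash",
    "seed",
    "package_version",
    "blocks"
  ],
  "title": "AnalysisReport",
  "type": "object"
}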