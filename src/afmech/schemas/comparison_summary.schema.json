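{
  "$defs": {
    "ProtocolSummary": {
      "properties": {
        "load_axis": {
          "title": "Load Axis",
          "type": "string"
        },
        "max_stress_ratio": {
          "title": "Max Stress Ratio",
          "type": "number"
        },
        "max_tangent_ratio": {
          "title": "Max Tangent Ratio",
          "type": "number"
        },
        "median_stress_pct_difference": {
          "title": "Median Stress Pct Difference",
          "type": "number"
        },
        "median_stress_ratio": {
          "title": "Median Stress Ratio",
          "type": "number"
        },
        "median_tangent_ratio": {
          "title": "Median Tangent Ratio",
          "type": "number"
        },
        "n_points": {
          "title": "N Points",
          "type": "integer"
        },
        "protocol": {
          "title": "Protocol",
          "type": "string"
        }
      },
      "required": [
        "protocol",
        "load_axis",
        "n_points",
        "max_stress_ratio",
        "median_stress_ratio",
        "max_tangent_ratio",
        "median_tangent_ratio",
        "median_stress_pct_difference"
      ],
      "title": "ProtocolSummary",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "JSON summary schema of a two-parameter-set comparison.",
  "properties": {
    "label_a": {
      "title": "Label A",
      "type": "string"
    },
    "label_b": {
      "title": "Label B",
      "type": "string"
    },
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "protocols": {
      "items": {
        "$ref": "#/$defs/ProtocolSummary"
      },
      "title": "Protocols",
      "type": "array"
    },
    "ratio_convention": {
      "title": "Ratio Convention",
      "type": "string"
    },
    "scope": {
      "title": "Scope",
      "type": "string"
    }
  },
  "required": [
    "label_a",
    "label_b",
    "ratio_convention",
    "scope",
    "package_version",
    "protocols"
  ],
  "title": "ComparisonSummary",
  "type": "object"
}
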