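{
  "$defs": {
    "EventReport": {
      "additionalProperties": false,
      "properties": {
        "gene_clade": {
          "items": {
            "type": "string"
          },
          "title": "Gene Clade",
          "type": "array"
        },
        "mapped_species": {
          "title": "Mapped Species",
          "type": "string"
        },
        "age_lower": {
          "title": "Age Lower",
          "type": "number"
        },
        "age_upper": {
          "title": "Age Upper",
          "type": "number"
        },
        "child_species": {
          "items": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "title": "Child Species",
          "type": "array"
        },
        "completeness": {
          "anyOf": [
            {
              "items": {
                "type": "number"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Completeness"
        },
        "verdict": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Verdict"
        },
        "wgd_matches": {
          "default": [],
          "items": {
            "additionalProperties": true,
            "type": "object"
          },
          "title": "Wgd Matches",
          "type": "array"
        }
      },
      "required": [
        "gene_clade",
        "mapped_species",
        "age_lower",
        "age_upper",
        "child_species"
      ],
      "title": "EventReport",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Schema of the JSON report written by the ``dfd`` and ``run`` commands.",
  "properties": {
    "n_leaves": {
      "title": "N Leaves",
      "type": "integer"
    },
    "outgroup": {
      "items": {
        "type": "string"
      },
      "title": "Outgroup",
      "type": "array"
    },
    "hybrids_excluded": {
      "items": {
        "type": "string"
      },
      "title": "Hybrids Excluded",
      "type": "array"
    },
    "clusters": {
      "additionalProperties": {
        "items": {
          "type": "string"
        },
        "type": "array"
      },
      "title": "Clusters",
      "type": "object"
    },
    "subclusters": {
      "additionalProperties": {
        "items": {
          "type": "string"
        },
        "type": "array"
      },
      "title": "Subclusters",
      "type": "object"
    },
    "coverage": {
      "additionalProperties": {
        "additionalProperties": {
          "type": "boolean"
        },
        "type": "object"
      },
      "title": "Coverage",
      "type": "object"
    },
    "events": {
      "items": {
        "$ref": "#/$defs/EventReport"
      },
      "title": "Events",
      "type": "array"
    },
    "n_duplications": {
      "title": "N Duplications",
      "type": "integer"
    },
    "n_losses": {
      "title": "N Losses",
      "type": "integer"
    },
    "dual_retainers": {
      "title": "Dual Retainers",
      "type": "integer"
    }
  },
  "required": [
    "n_leaves",
    "outgroup",
    "hybrids_excluded",
    "clusters",
    "subclusters",
    "coverage",
    "events",
    "n_duplications",
    "n_losses",
    "dual_retainers"
  ],
  "title": "Report",
  "type": "object"
}
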