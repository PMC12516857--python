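{
  "description": "Full generative specification of a synthetic cohort.\n\nDefaults (see :func:`default_study_config`) reproduce the sampling\nconditions of the adolescent study the package emulates.",
  "properties": {
    "N": {
      "exclusiveMinimum": 0,
      "title": "N",
      "type": "integer"
    },
    "female_fraction": {
      "maximum": 1,
      "minimum": 0,
      "title": "Female Fraction",
      "type": "number"
    },
    "orientation_probs": {
      "additionalProperties": {
        "additionalProperties": {
          "type": "number"
        },
        "type": "object"
      },
      "title": "Orientation Probs",
      "type": "object"
    },
    "gd_prob": {
      "maximum": 1,
      "minimum": 0,
      "title": "Gd Prob",
      "type": "number"
    },
    "gd_doubts_fraction": {
      "default": 0.9375,
      "maximum": 1,
      "minimum": 0,
      "title": "Gd Doubts Fraction",
      "type": "number"
    },
    "item_missing_probs": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Item Missing Probs",
      "type": "object"
    },
    "true_prevalence": {
      "additionalProperties": {
        "additionalProperties": {
          "type": "number"
        },
        "type": "object"
      },
      "title": "True Prevalence",
      "type": "object"
    },
    "gd_true_prevalence": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Gd True Prevalence"
    },
    "screening_sensitivity": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Screening Sensitivity",
      "type": "object"
    },
    "screening_specificity": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Screening Specificity",
      "type": "object"
    },
    "interview_response_prob": {
      "maximum": 1,
      "minimum": 0,
      "title": "Interview Response Prob",
      "type": "number"
    },
    "response_odds_multiplier_cases": {
      "default": 1.0,
      "exclusiveMinimum": 0,
      "title": "Response Odds Multiplier Cases",
      "type": "number"
    },
    "subcohort1_fraction": {
      "default": 0.5,
      "maximum": 1,
      "minimum": 0,
      "title": "Subcohort1 Fraction",
      "type": "number"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    }
  },
  "required": [
    "N",
    "female_fraction",
    "orientation_probs",
    "gd_prob",
    "true_prevalence",
    "screening_sensitivity",
    "screening_specificity",
    "interview_response_prob"
  ],
  "title": "SyntheticCohortConfig",
  "type": "object"
}
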