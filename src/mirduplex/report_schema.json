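{
  "type": "object",
  "required": ["seed", "study", "predictors", "combinations", "features", "energy_trend"],
  "properties": {
    "seed": {"type": "integer"},
    "study": {
      "type": "object",
      "required": ["n_tp", "n_fn", "n_decoys", "n_negative_pairs"],
      "properties": {
        "n_tp": {"type": "integer"},
        "n_fn": {"type": "integer"},
        "n_decoys": {"type": "integer"},
        "n_negative_pairs": {"type": "integer"}
      }
    },
    "predictors": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": [
          "cutoff", "n_predictions", "confusion_default", "precision", "recall",
          "threshold_curve", "optimal_score", "confusion_at_optimal", "auc"
        ],
        "properties": {
          "cutoff": {"type": "number"},
          "n_predictions": {"type": "integer"},
          "mean_predictions_per_mirna": {"type": "number"},
          "confusion_default": {"type": "object"},
          "precision": {"type": "number"},
          "recall": {"type": "number"},
          "specificity": {"type": "number"},
          "sensitivity": {"type": "number"},
          "threshold_curve": {
            "type": "object",
            "required": ["thresholds", "precision", "recall"],
            "properties": {
              "thresholds": {"type": "array", "items": {"type": "number"}},
              "precision": {"type": "array", "items": {"type": "number"}},
              "recall": {"type": "array", "items": {"type": "number"}}
            }
          },
          "optimal_score": {"type": ["number", "null"]},
          "confusion_at_optimal": {"type": "object"},
          "precision_at_optimal": {"type": "number"},
          "recall_at_optimal": {"type": "number"},
          "auc": {"type": ["number", "null"]}
        }
      }
    },
    "combinations": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["mode", "confusion", "precision", "recall"],
        "properties": {
          "mode": {"type": "string"},
          "confusion": {"type": "object"},
          "precision": {"type": "number"},
          "recall": {"type": "number"}
        }
      }
    },
    "features": {
      "type": "object",
      "required": ["n_tp", "n_fn", "rank_tests", "entropy_profiles", "cluster_leaf_order"],
      "properties": {
        "n_tp": {"type": "integer"},
        "n_fn": {"type": "integer"},
        "rank_tests": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["statistic", "pvalue"],
            "properties": {
              "statistic": {"type": "number"},
              "pvalue": {"type": "number"}
            }
          }
        },
        "entropy_profiles": {
          "type": "object",
          "additionalProperties": {"type": "array", "items": {"type": "number"}}
        },
        "cluster_leaf_order": {"type": "array", "items": {"type": "integer"}}
      }
    },
    "energy_trend": {
      "type": "object",
      "required": ["spearman_rho", "spearman_pvalue", "smoothed_first", "smoothed_last", "n_records"],
      "properties": {
        "spearman_rho": {"type": "number"},
        "spearman_pvalue": {"type": "number"},
        "smoothed_first": {"type": "number"},
        "smoothed_last": {"type": "number"},
        "n_records": {"type": "integer"}
      }
    }
  }
}
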