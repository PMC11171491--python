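{
  "description": "Published inputs from a multicenter chest-radiograph AI evaluation: standalone-phase per-anomaly confusion counts (500 positive / 1000 negative images per anomaly), per-anomaly ROC AUCs, and nine-reader aided/unaided outcome means and SDs.",
  "confusion_counts": {
    "pleural_effusion": {"tp": 486, "fn": 14, "fp": 130, "tn": 870},
    "consolidation": {"tp": 465, "fn": 35, "fp": 114, "tn": 886},
    "cardiomegaly": {"tp": 489, "fn": 11, "fp": 161, "tn": 839},
    "pulmonary_nodule": {"tp": 494, "fn": 6, "fp": 205, "tn": 795},
    "pneumothorax": {"tp": 488, "fn": 12, "fp": 188, "tn": 812},
    "acute_pulmonary_edema": {"tp": 471, "fn": 29, "fp": 141, "tn": 859}
  },
  "per_anomaly_auc": {
    "pleural_effusion": 0.9362,
    "consolidation": 0.9161,
    "cardiomegaly": 0.9464,
    "pulmonary_nodule": 0.9582,
    "pneumothorax": 0.9457,
    "acute_pulmonary_edema": 0.9123
  },
  "n_readers": 9,
  "reader_summary": {
    "time_s": {
      "unaided": {"mean": 22.9, "sd": 2.3},
      "aided": {"mean": 14.7, "sd": 1.3}
    },
    "auc": {
      "unaided": {"mean": 0.759, "sd": 0.07},
      "aided": {"mean": 0.88, "sd": 0.05}
    },
    "sensitivity": {
      "unaided": {"mean": 0.769, "sd": 0.02},
      "aided": {"mean": 0.857, "sd": 0.02}
    },
    "specificity": {
      "unaided": {"mean": 0.946, "sd": 0.01},
      "aided": {"mean": 0.974, "sd": 0.01}
    }
  }
}
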