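n_positive_per_label: 500
n_negative_per_label: 1000
image_width: 1024
image_height: 1024
lesion_min_side: 48
lesion_max_side: 384
detectors:
- sensitivity: 0.955
  fp_rate: 0.15
  jitter_sd: 6.0
  tp_score:
  - 8.0
  - 2.0
  fp_score:
  - 2.0
  - 5.0
- sensitivity: 0.96
  fp_rate: 0.15
  jitter_sd: 6.0
  tp_score:
  - 8.0
  - 2.0
  fp_score:
  - 2.0
  - 5.0
- sensitivity: 0.965
  fp_rate: 0.15
  jitter_sd: 6.0
  tp_score:
  - 8.0
  - 2.0
  fp_score:
  - 2.0
  - 5.0
- sensitivity: 0.958
  fp_rate: 0.15
  jitter_sd: 6.0
  tp_score:
  - 8.0
  - 2.0
  fp_score:
  - 2.0
  - 5.0
- sensitivity: 0.962
  fp_rate: 0.15
  jitter_sd: 6.0
  tp_score:
  - 8.0
  - 2.0
  fp_score:
  - 2.0
  - 5.0
codetection_correlation: 0.8
shared_fp_rate: 1.0
shared_fp_fire_prob: 0.9
annotators:
- jitter_sd: 4.0
  miss_prob: 0.0
  spurious_prob: 0.0
- jitter_sd: 4.0
  miss_prob: 0.0
  spurious_prob: 0.0
- jitter_sd: 4.0
  miss_prob: 0.0
  spurious_prob: 0.0
n_readers: 9
unaided:
  sensitivity: 0.769
  specificity: 0.946
  auc: 0.759
  time_mean_s: 22.9
  time_sd_s: 2.3
  operating_sd: 0.02
  auc_sd: 0.07
  time_cv_within: 0.35
aided:
  sensitivity: 0.857
  specificity: 0.974
  auc: 0.88
  time_mean_s: 14.7
  time_sd_s: 1.3
  operating_sd: 0.02
  auc_sd: 0.05
  time_cv_within: 0.35
reader_positive_mix:
  consolidation: 77
  pleural_effusion: 60
  pneumothorax: 32
  cardiomegaly: 16
  acute_pulmonary_edema: 37
  pulmonary_nodule: 43
n_reader_negatives: 640
demographics:
  age_mean: 49.9
  age_sd: 23.0
  female_fraction: 0.545
  manufacturer_shares:
    GMM/Primax: 0.17
    Fujifilm: 0.11
    Shimadzu: 0.38
    Canon: 0.28
    Medecom: 0.06
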