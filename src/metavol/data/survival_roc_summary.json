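{
  "cohort_n": 70,
  "mean_os_months": 71.6,
  "mean_os_se": 7.4,
  "mean_os_ci": [57.2, 86.1],
  "mean_rfs_months": 38.7,
  "mean_rfs_se": 2.9,
  "mean_rfs_ci": [32.9, 44.6],
  "roc_mortality": {
    "suvmax_liver": {"auc": 0.726, "cutoff": 22, "direction": "low_positive", "sensitivity": 85.7},
    "hi2": {"auc": 0.661, "cutoff": 62.3, "direction": "high_positive", "specificity": 85.7}
  },
  "roc_relapse": {
    "ldh_u_per_l": {"auc": 0.675, "cutoff": 301, "direction": "high_positive"},
    "hi2": {"auc": 0.655, "cutoff": 87.9, "direction": "high_positive", "sensitivity": 79.3},
    "suvmax_liver": {"auc": 0.647, "cutoff": 21, "direction": "low_positive"}
  },
  "logrank_p": {
    "os_by_suvmax_liver_22": 0.003,
    "os_by_hi2_62_3": 0.013,
    "rfs_by_ldh_301": 0.002,
    "rfs_by_hi2_87_9": 0.001
  }
}
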