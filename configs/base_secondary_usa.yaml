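test:
  sensitivity: 0.928
  specificity: 0.915
  sd_sensitivity: 0.011
  sd_specificity: 0.019
cohort:
  size: 10000
  prevalence: 0.03
costs:
  currency: USD
  ct_scan: 163.0
  mri_scan: 380.0
  neurology_outpatient: 76.0
  gp_visit: 76.0
  monitoring_per_quarter: 154.0
  test_cost: 100.0
  fast_track_premium: 0.0
pathway:
  p_image_after_negative: 1.0
  consultation_addon: 0.0
  survival_summary: median
  delay_fast: 7.0
  delay_standard: 28.0
  delay_late: 56.0
  workup_costing: calibrated
  workup_visits:
  - - neurology_outpatient
    - 1.0
  ct_fraction: 0.0
outcomes:
  utility: 0.89
  horizon_days: 730.0
  qaly_gain_per_true_positive: 0.1898706896551724
  avoided_cost_per_skipped_workup: 488.4999368045463
  extra_monitoring_years_per_tp: 0.21401543301625045
  discount_rate: 0.0
  baseline_survival_days: 365.25
scenario: secondary
country: USA
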