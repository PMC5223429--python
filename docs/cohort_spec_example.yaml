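# Example cohort specification for `gdlaudit simulate --spec`.
#
# prevalence: contraindication id -> planted fraction (0-1) or exact count.
#   Paired thresholds must be consistent: the coarser predicate
#   (sbp_gt_184, dbp_gt_109, onset_gt_3h) must be >= its finer one.
# missingness: registry column -> exact fraction of cells to blank (MCAR).
# mode: exact-counts (default) plants counts exactly; sampled draws
#   binomial counts from the fractions.
mode: exact-counts
prevalence:
  nihss_gt_25: 0.011
  anticoagulation: 0.024
  sbp_gt_185: 0.025
  sbp_gt_184: 0.040
  dbp_gt_110: 0.008
  dbp_gt_109: 0.021
  diabetes_and_previous_stroke: 0.025
  glucose_lt_50_or_gt_400: 0.003
  age_gt_80: 0.089
  onset_gt_3h: 0.082
  onset_gt_4_5h: 0.009
missingness:
  glucose: 0.05
  nihss: 0.02
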