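# AVS-like shared-Berkson scenario: point doses with a coefficient of
# variation of 50% and perfect within-group dose correlation, one subject in
# twelve belonging to a sharing group of ~10 (shipmates / same-test blocks).
# Doses are "high sided" compensation-style estimates on a lognormal scale.
scenario: avs_like
dosimetry:
  n_subjects: 500
  frac_grouped: 0.0833333333  # one in twelve
  group_size: 10
  group_spread: 0.1           # log-SD of within-group dose spread
  cv: 0.5                     # dose CV; variance = 0.25 * dose^2
  dose_median: 0.1            # Gy
  dose_gsd: 2.5
outcome:
  family: gaussian_linear
  alpha0: 0.0
  sigma: 1.0
  # slope placed where the shared-error slope-variance inflation equals the
  # error-free OLS slope variance (calibrate_slope_for_inflation, ratio 1)
  beta: calibrated
  inflation_ratio: 1.0
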