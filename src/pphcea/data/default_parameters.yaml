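# Base-case inputs, deterministic sensitivity ranges and probabilistic
# distribution families for the carbetocin-vs-oxytocin PPH prevention model.
# Costs are 2022 USD (USD 1 = HKD 7.8); lengths of stay in days.
#
# A parameter without `range` is held fixed in one-way sensitivity analysis;
# a parameter without `distribution` is held fixed in probabilistic analysis.
# Beta shape parameters are re-derived from (base, range) by moment matching
# (mean = base, sd = range-width / 3.92, reading the range as a central 95%
# interval); triangular uses (min = low, mode = base, max = high).
parameters:
  # clinical cascade
  p_csection: {base: 0.304, range: [0.243, 0.365], distribution: beta}
  p_pph_oxy_vaginal: {base: 0.022, range: [0.018, 0.026], distribution: beta}
  p_pph_oxy_csection: {base: 0.110, range: [0.088, 0.132], distribution: beta}
  rr_carbetocin: {base: 0.72, range: [0.56, 0.93], distribution: triangular}
  p_massive_given_pph_vaginal: {base: 0.1234, range: [0.0987, 0.1481], distribution: beta}
  p_massive_given_pph_csection: {base: 0.1513, range: [0.1210, 0.1816], distribution: beta}
  p_hysterectomy_given_massive: {base: 0.079, range: [0.063, 0.095], distribution: beta}
  p_death_given_hysterectomy: {base: 0.135, range: [0.0, 0.162], distribution: beta}
  # utility
  maternal_age: {base: 33, range: [18, 45], distribution: triangular}
  utility_baseline: {base: 0.92}
  disutility_pph_no_hyst: {base: 0.347, range: [0.1, 0.7], distribution: triangular}
  disutility_pph_hyst: {base: 0.435, range: [0.1, 0.7], distribution: triangular}
  # length of hospital stay
  los_vaginal_no_pph: {base: 2.38, range: [1.90, 2.86], distribution: triangular}
  los_csection_no_pph: {base: 4.52, range: [3.62, 5.42], distribution: triangular}
  los_second_line: {base: 6.0, range: [3.0, 53.0], distribution: triangular}
  los_hysterectomy: {base: 6.7, range: [4.2, 9.2], distribution: triangular}
  los_pph_multiplier: {base: 1.264, range: [1.133, 1.395], distribution: triangular}
  # unit costs (USD)
  cost_prevention_oxytocin: {base: 1.03, range: [1.03, 4.10]}  # single 10 IU dose; dose range 10-40 IU
  cost_prevention_carbetocin: {base: 25.6}
  cost_uterotonic_treatment: {base: 63.0, range: [2.0, 182.0], distribution: triangular}
  cost_second_line: {base: 2765.0, range: [2247.0, 3318.0], distribution: triangular}
  cost_hysterectomy: {base: 11477.0, range: [10319.0, 12634.0], distribution: triangular}
  cost_day_general: {base: 654.0}
  cost_day_hdu: {base: 1750.0}
  cost_day_icu: {base: 3128.0}
  # day rates actually charged on PPH paths; upper limits are the HDU and
  # ICU rates for PPH without and with hysterectomy respectively
  cost_day_pph_no_hyst: {base: 654.0, range: [654.0, 1750.0], distribution: triangular}
  cost_day_pph_hyst: {base: 654.0, range: [654.0, 3128.0], distribution: triangular}
  # analysis settings
  annual_discount_rate: {base: 0.03}
  wtp_threshold: {base: 49630.0}
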