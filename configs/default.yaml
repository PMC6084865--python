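# Default analysis configuration (values shown are the package defaults;
# uncomment to override). Quantities and their meanings:
#
# window_quarters        running-mean detrend window for crop series
#                        (27 quarters ~ 7 years, one rice-genotype life cycle)
# sm_lead_quarters       soil moisture leads crops by one quarter (3 months)
# enso_sm_lead_months    Nino3.4 leads soil moisture by 4 months
# enso_crop_lead_months  Nino3.4 leads crops by 7 months
# confidence             two-tailed significance level for correlation maps
# display_mask           |r| below this is masked (white) in map tables
# n_eff_national         effective sample size = number of years (df = 28)
# warming_targets        global-mean warming targets [deg C]
# envelope_threshold_c   quarterly temperature tolerance bound for rice
# envelope_rescale       display rescaling of occurrence histogram counts

window_quarters: 27
sm_lead_quarters: 1
enso_sm_lead_months: 4
enso_crop_lead_months: 7
confidence: 0.90
display_mask: 0.3
n_eff_national: 30
warming_targets: [2.0, 4.0]
histogram_bin_width: 0.5
envelope_threshold_c: 28.0
envelope_rescale: 4.0
seed: 0

sim:
  n_years: 30
  seed: 0
  # crops:
  #   missing_fraction: 0.01
  #   systems:
  #     rainfed:
  #       coupling: 0.5
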