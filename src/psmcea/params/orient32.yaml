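# Model inputs: first-line unresectable HCC, sintilimab + bevacizumab
# biosimilar vs sorafenib, Chinese healthcare-system perspective (2020 USD).
# Point estimates with (low, high) ranges; `dist` is the PSA distribution.
# Structural assumptions that the source analysis leaves open are grouped
# under `assumptions` and documented in docs/methods.md.

model:
  cycle_days: 21
  horizon_years: 30          # "lifetime" horizon
  annual_discount: 0.03
  days_per_month: 30.4375
  half_cycle_correction: true
  wtp_per_qaly: 30552        # 3x 2020 Chinese per-capita GDP, $/QALY

survival:
  # parametric fits to the digitized sorafenib-arm trial curves (months)
  sorafenib_pfs: {family: lognormal, params: [1.121355, 0.7702185]}    # mu, sigma
  sorafenib_os: {family: loglogistic, params: [0.01822555, 1.694566]}  # lam, gamma

hazard_ratios:   # combination vs sorafenib
  pfs: {base: 0.560, low: 0.460, high: 0.700, dist: lognormal}
  os: {base: 0.570, low: 0.430, high: 0.750, dist: lognormal}

utilities:
  pfd: {base: 0.760, low: 0.610, high: 0.910, dist: beta}
  pd: {base: 0.680, low: 0.540, high: 0.820, dist: beta}
  ae_disutility_g12: {base: 0.010, low: 0.008, high: 0.020, dist: beta}
  ae_disutility_g3plus: {base: 0.160, low: 0.110, high: 0.204, dist: beta}

ae_costs:   # $ per grade >=3 event managed
  ast_increase: {base: 87, low: 70, high: 105, dist: gamma}
  platelet_decrease: {base: 1054, low: 843, high: 1265, dist: gamma}
  bilirubin_increase: {base: 114, low: 91, high: 136, dist: gamma}
  hypertension: {base: 1.35, low: 1.08, high: 1.62, dist: gamma}
  ppe: {base: 34, low: 27, high: 40, dist: gamma}   # palmar-plantar erythrodysesthesia

drug_costs:   # $ per 21-day cycle
  sintilimab: {base: 804, low: 643, high: 965, dist: gamma}
  bevacizumab_biosimilar: {base: 1465, low: 1172, high: 1758, dist: gamma}
  sorafenib: {base: 790, low: 632, high: 948, dist: gamma}
  test: {base: 352, low: 282, high: 423, dist: gamma}
  pembrolizumab: {base: 5069, low: 4055, high: 6082, dist: gamma}
  regorafenib: {base: 1747, low: 1397, high: 2096, dist: gamma}
  bsc: {base: 357, low: 286, high: 428, dist: gamma}

arms:
  sorafenib:
    first_line_drugs: [sorafenib]      # 400 mg BID, oral
    treatment_cap_months: null         # treated until progression
    subsequent_therapy:
      proportion: {base: 0.470, low: 0.376, high: 0.564, dist: beta}
      drug: pembrolizumab              # immune agent after TKI failure
    ae_incidence:
      ast_increase: {base: 0.05, low: 0.040, high: 0.060, dist: beta}
      platelet_decrease: {base: 0.03, low: 0.024, high: 0.036, dist: beta}
      bilirubin_increase: {base: 0.03, low: 0.024, high: 0.036, dist: beta}
      hypertension: {base: 0.06, low: 0.048, high: 0.072, dist: beta}
      ppe: {base: 0.12, low: 0.096, high: 0.144, dist: beta}
  combination:
    first_line_drugs: [sintilimab, bevacizumab_biosimilar]  # 200 mg + 15 mg/kg @ 60 kg q3w
    treatment_cap_months: 24           # first-line treatment capped at 24 months
    subsequent_therapy:
      proportion: {base: 0.290, low: 0.232, high: 0.348, dist: beta}
      drug: regorafenib                # TKI after immunotherapy failure
    ae_incidence:
      ast_increase: {base: 0.020, low: 0.016, high: 0.024, dist: beta}
      platelet_decrease: {base: 0.08, low: 0.064, high: 0.096, dist: beta}
      bilirubin_increase: {base: 0.05, low: 0.040, high: 0.060, dist: beta}
      hypertension: {base: 0.14, low: 0.112, high: 0.168, dist: beta}
      ppe: {base: 0.0, low: 0.0, high: 0.0, dist: beta}

assumptions:
  subsequent_max_cycles: 6    # cycles of second-line therapy per progressor
  ae_duration_cycles: 1       # duration of one grade >=3 AE episode
  test_cost_in_pd: true       # routine monitoring continues after progression
  intervention: combination
  comparator: sorafenib
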