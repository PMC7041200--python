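# Base-case model inputs for the annual preventive dental intervention
# cost-utility analysis.  Costs are AUD (2018 fee schedule); probabilities
# for new caries are on the observed 2-year scale and converted to annual
# at model-build time.
settings:
  horizon_cycles: 10
  cycle_length_years: 1.0
  discount_rate_costs: 0.05
  discount_rate_qalys: 0.0
  cohort_size: 500
  wtp: 50000
  fraction_plaque_calculus: 0.50
  fraction_ohi_diet: 0.25
  fraction_sealant: 1.0
  treated_return_convention: seek_times_mix
  probability_conversion: proportion_as_rate
  accrual_timing: cycle_end
  include_initial_lesions: false

shared:
  p_restoration:   {base: 0.40, rel_bound: 0.15, dist: fixed, scale: probability, source: study treatment mix}
  p_extraction:    {base: 0.06, rel_bound: 0.15, dist: fixed, scale: probability, source: study treatment mix}
  p_pulp_therapy:  {base: 0.04, rel_bound: 0.15, dist: fixed, scale: probability, source: study treatment mix}
  cost_examination:     {base: 53, low: 48, high: 78, dist: fixed, scale: currency, source: fee schedule}
  cost_restoration:     {base: 145, low: 117, high: 229, dist: gamma, scale: currency, source: fee schedule weighted mean}
  cost_extraction:      {base: 195, low: 84, high: 442, dist: fixed, scale: currency, source: fee schedule}
  cost_pulp_therapy:    {base: 77, low: 31, high: 538, dist: fixed, scale: currency, source: fee schedule weighted mean}
  cost_fissure_sealant: {base: 47, low: 42, high: 47, dist: fixed, scale: currency, source: fee schedule}
  cost_radiography:     {base: 38, low: 31, high: 95, dist: fixed, scale: currency, source: fee schedule bitewing}
  cost_varnish:         {base: 30, dist: fixed, scale: currency, source: fee schedule}
  cost_plaque_removal:  {base: 55, dist: fixed, scale: currency, source: fee schedule}
  cost_calculus_removal: {base: 91, low: 82, high: 91, dist: fixed, scale: currency, source: fee schedule}
  cost_oral_hygiene_instructions: {base: 50, dist: fixed, scale: currency, source: fee schedule}
  cost_dietary_advice:  {base: 37, dist: fixed, scale: currency, source: fee schedule}
  utility_caries:  {base: 0.87, low: 0.80, high: 0.90, dist: fixed, scale: utility, source: CHU-9D}
  utility_healthy: {base: 1.00, low: 0.95, high: 1.00, dist: fixed, scale: utility}

arms:
  intervention:
    p_caries_baseline: {base: 0.71, low: 0.65, high: 0.78, dist: beta, scale: probability, source: study data}
    p_new_caries:      {base: 0.479, low: 0.316, high: 0.545, dist: beta, scale: probability, interval_years: 2, source: 2-year follow-up}
    p_seek_treatment:  {base: 0.90, low: 0.68, high: 1.00, dist: triangular, scale: probability, source: study consent and national survey}
  comparison:
    p_caries_baseline: {base: 0.80, low: 0.74, high: 0.85, dist: beta, scale: probability, source: study data}
    p_new_caries:      {base: 0.637, low: 0.357, high: 0.714, dist: beta, scale: probability, interval_years: 2, source: 2-year follow-up}
    p_seek_treatment:  {base: 0.68, low: 0.63, high: 0.73, dist: triangular, scale: probability, source: national survey}

dsa:
  parameters:
    - comparison.p_caries_baseline
    - intervention.p_caries_baseline
    - comparison.p_new_caries
    - intervention.p_new_caries
    - comparison.p_seek_treatment
    - intervention.p_seek_treatment
    - shared.cost_restoration
    - shared.cost_fissure_sealant
    - shared.utility_caries

scenarios:
  equal_baseline_prevalence:
    intervention.p_caries_baseline: 0.80
  zero_baseline_prevalence:
    intervention.p_caries_baseline: 0.0
    comparison.p_caries_baseline: 0.0
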