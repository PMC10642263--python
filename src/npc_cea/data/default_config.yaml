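# Default analysis configuration: first-line tislelizumab + gemcitabine/cisplatin
# versus gemcitabine/cisplatin alone for recurrent/metastatic nasopharyngeal
# carcinoma, Chinese healthcare-system perspective, USD.
#
# Every uncertain parameter is {base, low, high, distribution}; ranges are the
# published one-way sensitivity ranges (plus/minus 20% of the mean unless the
# source states otherwise). Costs sample from gamma, probabilities/utilities
# from beta, the discount rate from a uniform distribution.

meta:
  currency: USD
  cny_per_usd: 7.0848      # stored for provenance; all inputs already in USD

model:
  cycle_length_months: 1.3798767967145791   # 6 weeks = 42 / 30.4375 days
  n_cycles: 87                              # 10-year horizon
  discount_rate: {base: 0.05, low: 0.0, high: 0.08, distribution: uniform}
  wtp_per_qaly: 36289.0                     # 3x Chinese per-capita GDP (2022)
  accrual: start                            # state rewards on start-of-cycle occupancy
  survival_time_unit: cycles                # fitted curves measure time in 6-week cycles
  chemo_duration_model_cycles: 2            # 4 three-weekly chemo cycles
  routine_cost_states: [pfs, pd]

survival:
  tislelizumab_chemo:
    os:  {family: weibull, scale: 0.005008, shape: 1.297713}
    pfs: {family: weibull, scale: 0.075560, shape: 0.950960}
  chemo:
    os:  {family: weibull, scale: 0.001060, shape: 2.027554}
    pfs: {family: weibull, scale: 0.034444, shape: 1.615226}

# Drug costs are per administration; doses_per_model_cycle maps 3-weekly
# dosing onto the 6-week model cycle (tislelizumab is costed per model cycle).
costs:
  tislelizumab:         {base: 778.0, low: 622.0, high: 934.0, distribution: gamma,
                         doses_per_model_cycle: 1}
  gemcitabine:          {base: 39.0, low: 31.0, high: 47.0, distribution: gamma,
                         doses_per_model_cycle: 2}
  cisplatin:            {base: 31.0, low: 25.0, high: 37.0, distribution: gamma,
                         doses_per_model_cycle: 2}
  second_line:          {base: 77.0, low: 62.0, high: 92.0, distribution: gamma,
                         doses_per_model_cycle: 2}
  laboratory:           {base: 97.0, low: 78.0, high: 116.0, distribution: gamma}
  tumor_imaging:        {base: 208.0, low: 166.0, high: 250.0, distribution: gamma}
  administration:       {base: 48.0, low: 38.0, high: 58.0, distribution: gamma}
  best_supportive_care: {base: 142.0, low: 114.0, high: 170.0, distribution: gamma}
  terminal_care:        {base: 1833.0, low: 1466.0, high: 2200.0, distribution: gamma}

# Management cost per grade >=3 adverse-event episode (one-time, at entry).
ae_costs:
  leukopenia:                      {base: 100.0, low: 80.0, high: 120.0, distribution: gamma}
  lymphocyte_count_decreased:      {base: 100.0, low: 80.0, high: 120.0, distribution: gamma}
  neutropenia:                     {base: 466.0, low: 373.0, high: 559.0, distribution: gamma}
  white_blood_cell_count_decreased: {base: 466.0, low: 373.0, high: 559.0, distribution: gamma}
  neutrophil_count_decreased:      {base: 466.0, low: 373.0, high: 559.0, distribution: gamma}
  anemia:                          {base: 537.0, low: 430.0, high: 644.0, distribution: gamma}
  platelet_count_decreased:        {base: 3588.0, low: 2870.0, high: 4306.0, distribution: gamma}

utilities:
  pfs: {base: 0.650, low: 0.520, high: 0.780, distribution: beta}
  pd:  {base: 0.520, low: 0.416, high: 0.624, distribution: beta}

arms:
  tislelizumab_chemo:
    post_discontinuation_rate: {base: 0.520, low: 0.416, high: 0.624, distribution: beta}
    ae_disutility: {base: 0.0070, low: 0.0056, high: 0.0084, distribution: beta}
    ae_risks:
      lymphocyte_count_decreased:      {base: 0.107, low: 0.086, high: 0.128, distribution: beta}
      platelet_count_decreased:        {base: 0.206, low: 0.165, high: 0.247, distribution: beta}
      leukopenia:                      {base: 0.206, low: 0.165, high: 0.247, distribution: beta}
      neutropenia:                     {base: 0.214, low: 0.171, high: 0.257, distribution: beta}
      neutrophil_count_decreased:      {base: 0.275, low: 0.220, high: 0.330, distribution: beta}
      anemia:                          {base: 0.298, low: 0.238, high: 0.358, distribution: beta}
      white_blood_cell_count_decreased: {base: 0.313, low: 0.250, high: 0.376, distribution: beta}
  chemo:
    post_discontinuation_rate: {base: 0.720, low: 0.576, high: 0.864, distribution: beta}
    ae_disutility: {base: 0.0069, low: 0.0055, high: 0.0083, distribution: beta}
    ae_risks:
      lymphocyte_count_decreased:      {base: 0.121, low: 0.097, high: 0.145, distribution: beta}
      leukopenia:                      {base: 0.159, low: 0.127, high: 0.191, distribution: beta}
      neutropenia:                     {base: 0.189, low: 0.151, high: 0.227, distribution: beta}
      platelet_count_decreased:        {base: 0.258, low: 0.206, high: 0.310, distribution: beta}
      anemia:                          {base: 0.273, low: 0.218, high: 0.328, distribution: beta}
      neutrophil_count_decreased:      {base: 0.348, low: 0.278, high: 0.418, distribution: beta}
      white_blood_cell_count_decreased: {base: 0.371, low: 0.297, high: 0.445, distribution: beta}

psa:
  n_iterations: 10000
  sd_divisor: 3.92          # SD = (high - low) / (2 * 1.96)

# Insurance co-payment scenario: fraction of each listed price entering the
# payer-perspective cost. Second-line therapy is costed as capecitabine.
scenario_copayment:
  gemcitabine: 0.20
  cisplatin: 0.0
  capecitabine: 0.05
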