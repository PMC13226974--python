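# Two-strategy cost-utility model: open reduction and internal fixation
# (ORIF) vs primary tibiotalocalcaneal (TTC) nailing for fragility ankle
# fractures in adults aged >=75.  Complication probabilities are pooled
# cumulative incidences (McDonald 2025 meta-analysis); costs are 2024 USD
# from CMS reimbursement; utilities are EQ-5D weights (van Gerven et al).
#
# The reoperation event cost has no published value for this problem; with
# reoperation_cost_rule: index_cost each arm's own index cost is charged
# per reoperation.  Set strategies[].reoperation_cost to override.
cohort_label: "fragility ankle fracture, age >=75"
horizon_years: 4
discount_rate_annual: 0.03
options:
  half_cycle: false
  event_window: first_year
  reoperation_cost_rule: index_cost
states:
  - id: stable
    name: Stable community dwelling
    kind: permanent
    utility_annual: 0.90
  - id: superficial
    name: Superficial infection
    kind: temporary
    utility_annual: 0.78
  - id: reoperation
    name: Reoperation
    kind: temporary
    utility_annual: 0.78
strategies:
  - name: ORIF
    index_cost: 25000
    p_superficial: 0.102
    p_deep: 0.025
    p_nonunion: 0.117
    p_hardware: 0.066
    superficial_cost: 2500
  - name: TTC
    index_cost: 28000
    p_superficial: 0.021
    p_deep: 0.0343
    p_nonunion: 0.053
    p_hardware: 0.088
    superficial_cost: 2500
parameters:
  - {name: p_superficial_ORIF, base: 0.102, low: 0.082, high: 0.122, family: beta,
     targets: [strategies.ORIF.p_superficial], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: p_superficial_TTC, base: 0.021, low: 0.017, high: 0.025, family: beta,
     targets: [strategies.TTC.p_superficial], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: p_deep_ORIF, base: 0.025, low: 0.020, high: 0.030, family: beta,
     targets: [strategies.ORIF.p_deep], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: p_deep_TTC, base: 0.0343, low: 0.027, high: 0.041, family: beta,
     targets: [strategies.TTC.p_deep], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: p_nonunion_ORIF, base: 0.117, low: 0.084, high: 0.150, family: beta,
     targets: [strategies.ORIF.p_nonunion], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: p_nonunion_TTC, base: 0.053, low: 0.038, high: 0.068, family: beta,
     targets: [strategies.TTC.p_nonunion], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: p_hardware_ORIF, base: 0.066, low: 0.048, high: 0.084, family: beta,
     targets: [strategies.ORIF.p_hardware], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: p_hardware_TTC, base: 0.088, low: 0.068, high: 0.108, family: beta,
     targets: [strategies.TTC.p_hardware], units: probability,
     source: McDonald 2025 meta-analysis}
  - {name: index_cost_ORIF, base: 25000, low: 20000, high: 30000, family: gamma,
     targets: [strategies.ORIF.index_cost], units: USD 2024,
     source: CMS 2024 reimbursement}
  - {name: index_cost_TTC, base: 28000, low: 22400, high: 33600, family: gamma,
     targets: [strategies.TTC.index_cost], units: USD 2024,
     source: CMS 2024 reimbursement + implant premium}
  - {name: superficial_cost, base: 2500, low: 2000, high: 3000, family: gamma,
     targets: [strategies.ORIF.superficial_cost, strategies.TTC.superficial_cost],
     units: USD 2024, source: CMS 2024 reimbursement}
  - {name: utility_stable, base: 0.90, low: 0.80, high: 1.00, family: fixed,
     targets: [states.stable.utility_annual], units: EQ-5D,
     source: van Gerven et al}
  - {name: utility_temporary, base: 0.78, low: 0.68, high: 0.88, family: beta,
     targets: [states.superficial.utility_annual, states.reoperation.utility_annual],
     units: EQ-5D, source: van Gerven et al}
run:
  analysis: all
  n_iterations: 10000
  seed: 20240
  wtp_max: 300000
  wtp_step: 1000
  wtp_headline: 100000
  output_dir: results
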