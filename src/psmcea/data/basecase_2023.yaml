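settings:
  cycle_length_months: 1.0
  discount_rate: 0.05
  survival_floor: 0.01
  max_cycles: 480
  wtp: 35007.0
  occupancy: cycle_start
strategies:
  gumarontinib:
    drug_cost_pfs_cycle: 2921.9
    drug_cost_pd_cycle: 731.82
    utility_pfs: 0.804
    utility_pd: 0.321
    end_of_life_cost: 7554.01
    initial_visit_cost: 498.8
    pfs_management_cycle: 4.87
    pd_management_cycle: 20.613333333333333
    adverse_events:
    - name: peripheral_oedema
      incidence: 0.085
      cost: 0.16
      disutility: 0.05
      duration_years: 0.08333333333333333
    - name: headache
      incidence: 0.033
      cost: 1.94
      disutility: 0.07
      duration_years: 0.08333333333333333
    dose_mix:
      full_dose: 300
      counts:
        300: 84
        200: 8
  savolitinib:
    drug_cost_pfs_cycle: 3132.03
    drug_cost_pd_cycle: 731.82
    utility_pfs: 0.804
    utility_pd: 0.321
    end_of_life_cost: 7554.01
    initial_visit_cost: 498.8
    pfs_management_cycle: 4.87
    pd_management_cycle: 20.613333333333333
    adverse_events:
    - name: alt_increased
      incidence: 0.029
      cost: 116.29
      disutility: 0.061
      duration_years: 0.08333333333333333
    - name: ast_increased
      incidence: 0.029
      cost: 116.29
      disutility: 0.061
      duration_years: 0.08333333333333333
    dose_mix:
      full_dose: 600
      counts:
        600: 62
        400: 8
curves:
  gumarontinib:
    os:
      family: exponential
      params:
        rate: 0.04397
    pfs:
      family: lognormal
      params:
        meanlog: 2.029
        sdlog: 1.321
  savolitinib:
    os:
      family: exponential
      params:
        rate: 0.04427
    pfs:
      family: lognormal
      params:
        meanlog: 1.945
        sdlog: 1.222
dsa_ranges:
- paths:
  - strategies.gumarontinib.drug_cost_pfs_cycle
  low: 2377.37
  high: 3352.38
  label: Gumarontinib cycle cost (PFS)
- paths:
  - strategies.savolitinib.drug_cost_pfs_cycle
  low: 2548.34
  high: 3593.47
  label: Savolitinib cycle cost (PFS)
- paths:
  - strategies.gumarontinib.drug_cost_pd_cycle
  - strategies.savolitinib.drug_cost_pd_cycle
  low: 595.43
  high: 839.63
  label: Pemetrexed + cisplatin cycle cost (PD)
- paths:
  - strategies.gumarontinib.utility_pfs
  - strategies.savolitinib.utility_pfs
  low: 0.589
  high: 0.883
  label: Utility PFS
- paths:
  - strategies.gumarontinib.utility_pd
  - strategies.savolitinib.utility_pd
  low: 0.258
  high: 0.366
  label: Utility PD
- paths:
  - strategies.gumarontinib.end_of_life_cost
  - strategies.savolitinib.end_of_life_cost
  low: 6146.25
  high: 8666.94
  label: Terminal care cost
- paths:
  - strategies.gumarontinib.initial_visit_cost
  - strategies.savolitinib.initial_visit_cost
  low: 405.84000000000003
  high: 572.29
  label: Initial visit cost
- paths:
  - strategies.gumarontinib.pfs_management_cycle
  - strategies.savolitinib.pfs_management_cycle
  low: 3.9666666666666663
  high: 5.586666666666667
  label: PFS management per cycle
- paths:
  - strategies.gumarontinib.pd_management_cycle
  - strategies.savolitinib.pd_management_cycle
  low: 16.776666666666667
  high: 23.65
  label: PD management per cycle
- paths:
  - settings.discount_rate
  low: 0.0
  high: 0.08
  label: Discount rate
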