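deprivation_weights:
  maori:
  - 0.15
  - 0.25
  - 0.6
  non_maori:
  - 0.4
  - 0.35
  - 0.25
disability_weights:
  breast:
    diagnosis: 0.194
    preterminal: 0.512
    remission: 0.174
    terminal: 0.52
  colon:
    diagnosis: 0.288
    preterminal: 0.539
    remission: 0.167
    terminal: 0.548
  lung:
    diagnosis: 0.469
    preterminal: 0.539
    remission: 0.315
    terminal: 0.548
entry_year: 2006
intervention:
  direct_monthly_cost: 2500.0
  discount_rate: 0.03
  effect: 0.2
life_table:
  annual_decline:
    maori: 0.0225
    non_maori: 0.0175
  base_year: 2006
  decline_horizon_year: 2026
phase_schedules:
  breast:
    cure_months: 240
    diagnosis_months: 6
    preterminal_months: 11
    terminal_months: 1
  colon:
    cure_months: 96
    diagnosis_months: 9
    preterminal_months: 3
    terminal_months: 1
  lung:
    cure_months: 72
    diagnosis_months: 5
    preterminal_months: 5
    terminal_months: 1
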