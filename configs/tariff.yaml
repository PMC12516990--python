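# Unit prices, SEK (2021-style PLACEHOLDERS - the real regional tariff
# documents are not redistributable; replace with actual values for use).
physician_consultation_cost: 1914
specialist_consultation_cost: 3214
avg_cost_per_drg_point: 29239
multipliers:
  physician: 1
  other_hcp: "2/5"
  group: "2/5"
  team: "3/2"
  group_team: "3/2"
  home: 2
  indirect: "1/3"
hcp_hourly_wage_with_social_contributions: 556
# gross monthly wage per 10-year age band, SEK (placeholders)
wage_by_age_band:
  30-39: 36100
  40-49: 39500
  50-59: 39900
  60-69: 37800
  70-79: 35000
  80-89: 35000
  90-99: 35000
social_contribution_rate: 0.3142
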