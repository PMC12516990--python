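# Regional fee and ceiling rules.  Ceilings are the published 2021
# values; per-contact template fees are placeholders.
outpatient_fee_by_type:
  primary: 200
  "primary:indirect": 0
  specialised_outpatient: 300
  polyclinical: 300
outpatient_annual_ceiling: 1150
inpatient_fee_per_night: 100
inpatient_window_ceiling: 1500
inpatient_window_days: 30
home_visit_surcharge: 100
drug_annual_ceiling: 2350
reimbursement_period_start: 0
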