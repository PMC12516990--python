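# Generator parameters for the default synthetic cohort.  Demographic
# marginals are synthetic fixtures, not a calibration to any real trial.
age_mean: 70.7
age_sd: 9.4
women_prob: 0.46
diagnosis_probs: [0.38, 0.52, 0.10]
living_alone_prob: 0.30

baseline_utility_mean: 0.78
baseline_utility_sd: 0.14
control_utility_slope: -0.030
arm_utility_slope_diff: 0.018
visit_noise_sd: 0.05

# per (arm, visit month); intervention roughly doubles post-baseline rates
missingness_prob_by_arm_and_visit:
  control: {0: 0.02, 3: 0.08, 6: 0.08, 12: 0.10, 24: 0.12}
  intervention: {0: 0.02, 3: 0.15, 6: 0.16, 12: 0.20, 24: 0.22}

event_rates:
  primary: {control: 20.0, intervention: 21.5}
  specialised_outpatient: {control: 6.5, intervention: 5.2}
  inpatient: {control: 1.4, intervention: 1.0}
  polyclinical: 0.15
  dispensation: 24.0

drg_missing_prob: 0.23
sick_leave_rate: 12.0
mortality_hazard: 0.045
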