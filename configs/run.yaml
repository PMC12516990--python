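# Full-pipeline configuration for `ceapipe run --config configs/run.yaml`.
out_dir: scratch/pipeline_out
seed: 1
synth_n_per_arm: 110
tariff_file: configs/tariff.yaml
copay_rules_file: configs/copay_rules.yaml
m_imputations: 20
bootstrap_b: 1000
log_level: INFO
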