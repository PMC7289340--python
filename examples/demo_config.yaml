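# End-to-end demo: simulate a 300-child cohort, build the sex-specific
# GRS, fit the male trajectory model, estimate effects and adiposity
# timing with a 50-iteration cluster bootstrap.
#   bmigrowth run --config examples/demo_config.yaml
out_dir: demo_results
seed: 7
sex: male
simulate:
  n_children: 300
knots: [0.7, 1.5, 10.0]
exposure: ebf
estimation: reml
ages: [7.0, 10.0, 15.0, 18.0]
grs_levels: [2.5, 7.5]
ebf_levels: [5.0]
bootstrap_B: 50
log_level: INFO
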