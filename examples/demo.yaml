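# Simulated mixed-ancestry cohort, analyzed end to end:
#   cllprs run-all --config examples/demo.yaml --seed 7
seed: 7
output_dir: cllprs_demo_run
simulation:
  n_per_group: {control: 900, LC_MBL: 140, HC_MBL: 60, CLL: 240}
  ancestry_mix: {EUR: 0.70, AFR: 0.25, EAS: 0.05}
  n_aim_snps: 300
qc:
  snp_call_min: 0.95
  sample_call_min: 0.90
  hwe_alpha: 1.0e-5
scoring:
  use_external_cutoffs: true   # published EA quintile boundaries
models:
  reference_quantile: Q3
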