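# End-to-end synthetic demo: simulate profiles, AS events, and a binding
# titration, then run the three analyses.  Usage:
#   minorsplice run --config configs/demo.yaml --out demo_out
seed: 42
stages: [profiles, events, emsa]
profiles:
  n_species: 60
  n_background: 500
  loss_rate: 1.0
  module_size: 8
  rho: 0.9
  top_k: 20
events:
  n_genes: 400
  frac_u12_genes: 0.25
  n_events: 2000
  aa_enrichment_fold: 3.0
  pr_min: 0.9
  dpsi_min: 0.05
emsa:
  kd_true: 2.14
  bmax_true: 1.0
  noise_sd: 0.02
  n_replicates: 3
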