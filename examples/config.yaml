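# End-to-end pipeline configuration for `pndeeg run`.
# All randomness derives from the master seed; per-stage seeds are spawned
# from it and recorded in the run manifest.
seed: 7
simulate: true
synth:
  # reduced cohort so the demo finishes quickly; drop this block to use the
  # full default design (8/8/8/30, 20:10 vulnerable:preserved)
  n_per_group: {young-sham: 2, aged-sham: 2, young-surgery: 4, aged-surgery: 10}
  vulnerable_fraction: 0.6
  baseline_duration_s: 10.0
  maintenance_duration_s: 120.0
  emergence_duration_s: {preserved: 150.0, vulnerable: 180.0}
eval:
  model_ids: [LR, RF]
  split_ratios: [0.7]
  seeds: [42]
  n_folds: 2
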