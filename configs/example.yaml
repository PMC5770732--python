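# Example run configuration for `restconn all --config configs/example.yaml`.
# Omitted keys fall back to the package defaults.
seed: 1
outdir: runs/example
cohort:
  n_per_group: 12
  grid: [16, 16, 8]
  n_volumes: 150
  n_networks: 6
ica:
  orders: [6, 8, 10]
  match_threshold: 0.4
groupstats:
  voxel_p: 0.01
  corrected_alpha: 0.05
  n_sims: 500
granger:
  order: 1
  relay: 3          # network index treated as the relay node
classify:
  alpha: 0.05
  svm_width: 0.5
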