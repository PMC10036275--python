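# Demo: synthetic 10-tree mixed-severity plot, fully seed-determined.
seed: 20240901
output: runs/demo
scene:
  n_trees: 10
  burned_fraction: 0.5
  min_spacing: 4.5
  consumed_fraction: 0.15
params:
  chm_cell: 0.10
  sigma: 0.05
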