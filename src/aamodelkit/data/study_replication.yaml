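# Replication template: drop in the real gcpREV dat file and the original
# 26-taxon simulation tree to reproduce the published study conditions.
# Replace the two paths below before running.
simulation_model: /path/to/gcpREV.dat
tree: /path/to/simulation_tree.nwk
site_lengths: [400, 1500, 8000]
replicates: 100
estimators:
  - {method: ml, freq_mode: est, init: counts, maxiter: 600, ftol: 1.0e-9}
comparison_models: [poisson]
tree_search:
  enabled: true
seed: 42
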