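# Desk-scale simulation study: ML estimation only, 10 replicates,
# 400- and 1,500-site alignments, tree searches at 400 sites.
simulation_model: surrogate_sim
tree: surrogate
site_lengths: [400, 1500]
replicates: 10
estimators:
  - {method: ml, freq_mode: est, init: counts, maxiter: 300, ftol: 1.0e-7}
comparison_models: [poisson, surrogate_near, surrogate_far]
tree_search:
  enabled: true
  site_lengths: [400]
  models: [ml_est, simulation, surrogate_far]
seed: 42
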