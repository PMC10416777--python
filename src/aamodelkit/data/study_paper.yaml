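# Paper-scale study design: 100 replicates of 400/1,500/8,000-site
# alignments, ML (F_est, F_emp) and Bayesian estimation, searches for every
# model at every length.  Expect very long run times (the Bayesian
# estimator alone runs 600,000 generations per replicate).
simulation_model: surrogate_sim
tree: surrogate
site_lengths: [400, 1500, 8000]
replicates: 100
estimators:
  - {method: ml, freq_mode: est, init: counts, maxiter: 600, ftol: 1.0e-9}
  - {method: ml, freq_mode: emp, init: counts, maxiter: 600, ftol: 1.0e-9}
  - {method: bayes}
comparison_models: [poisson, surrogate_near, surrogate_far]
tree_search:
  enabled: true
seed: 42
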