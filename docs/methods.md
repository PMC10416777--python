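# Methods

## Model

`aamodelkit` works with general time-reversible amino-acid substitution
models (GTR20). A model is a triple (R, π, α):

* **Exchangeabilities** R = {r_ij}: one symmetric relative rate per
  unordered residue pair — 190 values kept on the unit simplex, so 189 of
  them are free. Residues follow the PAML file order
  (A R N D C Q E G H I L K M F P S T W Y V).
* **Composition** π: 20 stationary frequencies.
* **Rate heterogeneity**: a discrete gamma distribution with shape α and
  `ncat` equal-probability categories (default 4). Category rates are the
  conditional means of the gamma(α, α) density over its quantile bins,
  computed with regularised incomplete-gamma functions, so the mean rate is
  exactly 1.

The instantaneous rate matrix has q_ij = r_ij·π_j off the diagonal, rows
summing to zero, and is rescaled so −Σ π_i q_ii = 1; branch lengths are
therefore expected substitutions per site. Transition matrices come from
the spectral decomposition of the symmetrised matrix
B = diag(√π)·Q·diag(1/√π), which is numerically stable and gives every
P(rt) per gamma category from one eigendecomposition.

## Likelihood

`log_likelihood` implements Felsenstein pruning over compressed site
patterns, with a per-node, per-(category, pattern) log-scale accumulator to
prevent underflow on deep trees. The gamma mixture averages the per-category
site likelihoods with equal weights. Missing or ambiguous residues
(X B Z J U O - ? . * ~) contribute a partial-likelihood vector of ones, so an
all-missing column contributes exactly zero log-likelihood.
`brute_force_log_likelihood` marginalises explicitly over all internal-node
states and is the exact oracle for trees with at most 4 internal nodes.

### Analytic gradients

The ML estimator does not use finite differences for the 209 simplex
parameters. A backward (pre-order) pass computes, for every edge and
category, the sensitivity matrix S_e = ∂logL/∂P_e; the derivative with
respect to any model parameter θ then follows from the Fréchet derivative of
the matrix exponential through the eigendecomposition,
∂P/∂θ = D⁻¹V (G ∘ VᵀdB/dθ V) VᵀD with G the divided-difference kernel
(e^{λ_x t}−e^{λ_y t})/(λ_x−λ_y). Because dB/dθ is shared across edges, the
per-edge contributions collapse into a single 20×20 accumulator, and the
full 190-dimensional exchangeability gradient plus the 20-dimensional
composition gradient (including the root-prior and √π-conjugation terms and
the mean-rate normalisation) cost roughly four likelihood evaluations
instead of ~380. A dedicated test verifies the gradient against central
finite differences at step 1e-6; a second test checks the exact
orthogonality g·r = 0 implied by the scale invariance of the rescaled rate
matrix. Only the α derivative uses a central difference on log α.

## Estimation

`estimate_ml` maximises the likelihood on a fixed tree (topology and branch
lengths) over softmax transforms of the exchangeability simplex (189 free
logits), optionally the composition simplex (19 logits, frequency mode
F_est), and log α, with L-BFGS-B. Frequency modes mirror the three
protocols in use: F_mod (supplied, fixed), F_emp (alignment counts, fixed),
F_est (optimised). Default initialisation is the Poisson model with
empirical composition and α = 1; `init="counts"` starts instead from
pairwise mismatch counts normalised by frequency products, which typically
lands within r ≈ 0.9 of the optimum and cuts iterations substantially — the
study pipeline uses it. Convergence uses L-BFGS-B's relative-improvement
criterion (`ftol`, default 1e-9) plus the projected-gradient test; a
non-finite start triggers one restart from the Poisson model.

`estimate_bayes` is a Metropolis–Hastings sampler: Dirichlet-centred
proposals on both simplexes (proposal concentration κ·current state), a
multiplicative window on α, flat Dirichlet priors and an Exponential(1)
prior on α. One kernel fires per generation in rotation. Proposal scales
are auto-tuned toward 20–50% acceptance during the first 10% of generations
(inside the burn-in) and then frozen. The default schedule is 600,000
generations sampled every 100 (6,000 samples, 1,000 discarded), and the
returned model is the coordinate-wise mean of the post-burn-in samples —
each sample lies on the simplex, so the mean does too. The priors and
kernels are this package's own declared choices; the sampler is validated
by determinism, an α-credible-interval smoke test, and a scaled-down
Bernstein–von Mises check against the ML estimate.

## Simulation

`simulate_alignment` draws a root sequence i.i.d. from π, assigns each site
one gamma category for the whole tree (site-constant rates, matching the
Γ-mixture likelihood used for scoring), and samples child states from the
exact transition matrix P(r_c·b) per branch and category — no event-level
(Gillespie) simulation. A master seed spawns per-replicate child seeds via
`numpy.random.SeedSequence`, so any replicate is reproducible in isolation.
No indels or missing data are generated.

`random_tree` builds a uniform random unrooted binary topology by sequential
random edge addition, with exponential branch lengths rescaled to an exact
total length. `random_model` draws Dirichlet exchangeabilities/composition
and a log-uniform α ∈ [0.2, 5] (test plumbing).

### Bundled fixtures and what they emulate

The study that this package reproduces simulated data under an external
chloroplast model and a published 26-taxon tree (total length 7.74), neither
of which is redistributable here; seeded synthetic surrogates stand in:

* `surrogate_sim.dat` — exchangeabilities log-normal(σ = 1.6), composition
  Dirichlet(20), α = 0.8. The log-normal spread matches the several-orders-
  of-magnitude rate variation of empirical amino-acid matrices. (A flat
  Dirichlet(1) draw is far more skewed than any published matrix and, in a
  pilot, capped exchangeability recovery near r ≈ 0.94 even at 8,000
  sites.)
* `surrogate_near.dat` — a convex blend with the simulation model
  (L1 ≈ 0.56 on the simplex), playing the related-empirical-model role.
* `surrogate_far.dat` — an independent, *flatter* draw (σ = 0.5,
  L1 ≈ 1.28), playing the general-purpose empirical model role. Flatness is
  deliberate: averaged models underestimate multiple hits on data generated
  by a sharper process, which is what makes them infer shorter trees — the
  qualitative signature the study reports for general empirical models.
* `surrogate_tree.nwk` — seeded 26-taxon random tree rescaled to total
  length 7.74. Only the taxon count and total length of the original tree
  are known, so the branch-length profile is a package choice.

Real model files (gcpREV, cpREV, WAG) drop in anywhere a fixture name is
accepted; `study_replication.yaml` is the template for rerunning the full
design with the original inputs. What passing tests show is therefore that
the machinery reproduces the study's *patterns* under surrogate conditions;
absolute published numbers depend on the non-redistributable inputs.

## Tree search

`starting_tree` is neighbor joining (scikit-bio) on pairwise two-sequence
ML distances (Brent, bounds [1e-8, 20]); negative NJ lengths clamp to 1e-8.
`optimize_branch_lengths` sweeps edges depth-first, refreshing partial
likelihoods so every one-dimensional Brent problem is exact at the current
state; sweeps repeat until the per-sweep gain drops below 1e-6.
`search_ml_tree` evaluates both NNI rearrangements of every internal edge
with local re-optimisation of the five edges around the swap, accepts the
single best improving move (ties broken by the lexicographically smallest
canonical bipartition string), fully re-optimises branch lengths, and stops
when no move gains more than 1e-4 log units. Best-improvement acceptance
keeps the search path deterministic across platforms. SPR/TBR moves and
bootstrap support are out of scope.

## Evaluation

* RF distance: symmetric difference of nontrivial bipartitions; nRF divides
  by 2(n−3). WRF sums |Δ branch length| over the union of bipartitions
  *including* pendant edges (matched by leaf), counting a bipartition absent
  from one tree at its full length. Whether pendant edges belong in WRF is
  a convention choice; including them honours "the sum of the differences
  between all branch lengths" and is switchable by using the nontrivial
  table directly.
* PCA ordination: models map to their normalised 190-vectors — the full
  simplex vector is normalised even though only 189 of its entries are free
  (normalising over a 189-subset would break the symmetry between pairs) —
  optionally group-averaged, centred, and projected with scikit-learn's
  covariance PCA.
* Group comparison: Shapiro–Wilk on each group gates between the
  pooled-variance two-sample t-test (both normal at α = 0.05) and the
  Wilcoxon rank-sum test with normal approximation and tie correction; the
  F-test p-value for equality of variances is reported alongside. Pooled
  variance (not Welch) matches the F-test-then-t protocol. "Wilcoxon" is
  implemented as the two-sample rank-sum since the replicate sets are
  independent.

## Study pipeline

`run_simulation_study` is deterministic end to end given the master seed:
per-replicate seeds come from `SeedSequence(master, spawn_key=(index,))`.
Each replicate is simulated, estimated per configured method, and every
model (estimated, simulation, comparison fixtures) is scored on the fixed
simulation tree with its own composition and exchangeabilities and α as the
single free parameter — the "equal parameter counts" scoring convention that
makes raw log-likelihood scores comparable across models. Tree searches run
for the configured (site length, model) subsets; trees are compared to the
simulation tree by RF/WRF/nRF and total length. Aggregation contrasts each
model's replicate values against the simulation model's with
`compare_groups`; every aggregate is reproducible from the emitted
per-replicate table (tested).

Desk-scale defaults (shipped `study_desk.yaml`: 10 replicates, 400 and
1,500 sites, ML/F_est only, searches at 400 sites for the estimated model,
the simulation model and the far fixture) keep a full run in the
ten-to-fifteen-minute range on one core; `study_paper.yaml` records the full
design (100 replicates, three site lengths, F_est + F_emp + Bayesian
estimation, searches everywhere), which is a multi-day run dominated by the
600,000-generation MCMC chains.

## Numerical choices and limitations

* Transition probabilities are clipped to [0, 1] and row-renormalised after
  eigen-reconstruction (residues of order 1e-16).
* Branch lengths live in [1e-8, 20]; α in [1e-3, 1e3].
* Frequencies of exactly zero (in files or empirical counts) are floored at
  1e-10 and renormalised with a logged warning, preserving irreducibility.
* Dat-file frequencies may deviate from sum 1 by up to 1e-3 and are then
  renormalised; larger deviations are errors.
* The brute-force likelihood oracle refuses > 4 internal nodes.
* The NNI search can in principle stop in a local optimum; the study-size
  data (≥ 400 sites, 26 taxa) recover the simulation topology from the NJ
  start in nearly all replicates, matching the source study's behaviour.
* Scores across models are compared on the same alignment only; nothing
  corrects for multiple testing (none was applied in the source design).
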