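"""Data-specific model estimation under a fixed tree.

Two estimators of the 189 free exchangeabilities (+ composition + gamma
shape) of a GTR20+Gamma model, both constrained to a supplied tree with
fixed topology and branch lengths:

* ``estimate_ml`` — maximum likelihood by quasi-Newton (L-BFGS-B) on
  unconstrained transforms: softmax coordinates for both simplexes (last
  logit pinned at zero, so exactly 189 + 19 free coordinates) and log(alpha).
  Exchangeability and composition gradients are analytic (see
  ``PruningEngine.log_likelihood_and_gradient``); the alpha derivative uses
  a central finite difference on log(alpha).

* ``estimate_bayes`` — Metropolis-Hastings with Dirichlet-centred proposals
  on both simplexes and a multiplicative window on alpha; flat Dirichlet
  priors on the simplexes, Exponential(1) prior on alpha.  The returned
  model is the posterior mean of the post-burn-in samples (each sample lies
  on the simplex, so the mean does too).

Composition handling follows the three protocols used by model-estimation
software: F_mod (supplied and fixed), F_emp (empirical counts, fixed), and
F_est (optimised / sampled).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .alphabet import N_FREE_EXCHANGEABILITIES, N_PAIRS, N_STATES
from .likelihood import Alignment, PruningEngine, SitePatterns, compress_patterns
from .model import SubstitutionModel, poisson_model
from .trees import PhyloTree

logger = logging.getLogger(__name__)


class FrequencyMode(str, enum.Enum):
    F_MOD = "mod"  # use a supplied composition, fixed
    F_EST = "est"  # optimise the composition
    F_EMP = "emp"  # empirical composition of the alignment, fixed


def empirical_frequencies(aln: Alignment | SitePatterns) -> np.ndarray:
    """Residue frequencies counted over all sequences and sites, missing
    symbols excluded; zero counts floored at 1e-10 and renormalised."""
    if isinstance(aln, Alignment):
        pats = compress_patterns(aln)
    else:
        pats = aln
    counts = np.zeros(N_STATES)
    for i in range(N_STATES):
        counts[i] = ((pats.patterns == i) * pats.weights[None, :]).sum()
    if counts.sum() == 0:
        raise ValueError("alignment contains no canonical residues")
    freqs = counts / counts.sum()
    if np.any(freqs == 0):
        logger.warning("flooring %d unobserved residue frequencies", int((freqs == 0).sum()))
        freqs = np.maximum(freqs, 1e-10)
        freqs /= freqs.sum()
    return freqs


def counts_initial_model(aln: Alignment | SitePatterns, ncat: int = 4) -> SubstitutionModel:
    """Cheap data-driven starting model: exchangeabilities proportional to
    observed mismatch counts between all sequence pairs divided by the
    product of empirical frequencies; empirical composition; alpha = 1.

    Useful as an ``estimate_ml`` initialisation on larger data sets, where
    it starts the optimiser much closer to the optimum than the Poisson
    model does."""
    pats = compress_patterns(aln) if isinstance(aln, Alignment) else aln
    codes, w = pats.patterns, pats.weights
    n = codes.shape[0]
    counts = np.zeros((N_STATES, N_STATES))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            mask = (a < N_STATES) & (b < N_STATES) & (a != b)
            np.add.at(counts, (a[mask], b[mask]), w[mask])
    counts = counts + counts.T
    pi = empirical_frequencies(pats)
    rate = counts / np.outer(pi, pi)
    from .alphabet import PAIR_INDICES

    ex = np.array([rate[i, j] for i, j in PAIR_INDICES])
    positive = ex[ex > 0]
    floor = positive.min() * 0.1 if positive.size else 1.0
    ex = np.maximum(ex, floor)
    return SubstitutionModel(ex / ex.sum(), pi, alpha=1.0, ncat=ncat, name="counts-init")


def optimize_alpha(
    aln: Alignment | SitePatterns, tree: PhyloTree, model: SubstitutionModel
) -> tuple[float, float]:
    """Re-optimise only the gamma shape of a fixed model on a fixed tree.

    Returns (log-likelihood, alpha).  This is how fixed-rate models are
    scored for comparison: exchangeabilities and composition stay fixed and
    alpha is the single free parameter.
    """
    from scipy.optimize import minimize_scalar

    pats = compress_patterns(aln) if isinstance(aln, Alignment) else aln
    engine = PruningEngine(tree, pats)

    def neg(log_a):
        engine.set_parameters(
            model.exchangeabilities, model.composition, float(np.exp(log_a)), model.ncat
        )
        return -engine.log_likelihood()

    res = minimize_scalar(neg, bounds=(math.log(_ALPHA_MIN), math.log(_ALPHA_MAX)), method="bounded", options={"xatol": 1e-6})
    return float(-res.fun), float(np.exp(res.x))


@dataclass
class EstimationResult:
    model: SubstitutionModel
    log_likelihood: float
    n_evaluations: int
    n_iterations: int
    converged: bool
    settings: dict = field(default_factory=dict)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _logits(p: np.ndarray) -> np.ndarray:
    """Inverse of _softmax with the last coordinate pinned at zero."""
    lp = np.log(np.maximum(p, 1e-12))
    return lp - lp[-1]


_ALPHA_MIN, _ALPHA_MAX = 1e-3, 1e3


def estimate_ml(
    aln: Alignment | SitePatterns,
    tree: PhyloTree,
    freq_mode: FrequencyMode | str = FrequencyMode.F_EST,
    init: SubstitutionModel | str | None = None,
    composition: np.ndarray | None = None,
    ncat: int = 4,
    maxiter: int = 500,
    ftol: float = 1e-9,
) -> EstimationResult:
    """Maximum-likelihood GTR20+Gamma estimate on a fixed tree.

    The optimum always scores at least as high as the initialisation model
    (L-BFGS-B is monotone from its starting point).
    """
    freq_mode = FrequencyMode(freq_mode)
    pats = compress_patterns(aln) if isinstance(aln, Alignment) else aln
    engine = PruningEngine(tree, pats)

    if freq_mode is FrequencyMode.F_MOD:
        if composition is None:
            raise ValueError("freq_mode 'mod' requires a supplied composition")
        fixed_comp = np.asarray(composition, dtype=float)
    elif freq_mode is FrequencyMode.F_EMP:
        fixed_comp = empirical_frequencies(pats)
    else:
        fixed_comp = None

    if init is None or init == "poisson":
        base = poisson_model(alpha=1.0, ncat=ncat)
        init_comp = empirical_frequencies(pats) if fixed_comp is None else fixed_comp
        init = SubstitutionModel(base.exchangeabilities, init_comp, alpha=1.0, ncat=ncat, name="init")
    elif init == "counts":
        init = counts_initial_model(pats, ncat=ncat)
        if fixed_comp is not None:
            init = init.with_composition(fixed_comp)

    est_comp = freq_mode is FrequencyMode.F_EST
    nz_ex = N_FREE_EXCHANGEABILITIES  # 189
    nz_comp = N_STATES - 1 if est_comp else 0

    def unpack(theta: np.ndarray):
        z_ex = np.concatenate([theta[:nz_ex], [0.0]])
        ex = _softmax(z_ex)
        if est_comp:
            z_c = np.concatenate([theta[nz_ex : nz_ex + nz_comp], [0.0]])
            comp = _softmax(z_c)
        else:
            comp = fixed_comp
        alpha = float(np.exp(theta[-1]))
        alpha = min(max(alpha, _ALPHA_MIN), _ALPHA_MAX)
        return ex, comp, alpha

    n_eval = 0
    h_alpha = 1e-5

    def objective(theta: np.ndarray):
        nonlocal n_eval
        ex, comp, alpha = unpack(theta)
        engine.set_parameters(ex, comp, alpha, ncat)
        f, g_ex, g_comp = engine.log_likelihood_and_gradient()
        # central difference on log(alpha): two extra forward passes
        engine.set_parameters(ex, comp, alpha * math.exp(h_alpha), ncat)
        fp = engine.log_likelihood()
        engine.set_parameters(ex, comp, alpha * math.exp(-h_alpha), ncat)
        fm = engine.log_likelihood()
        g_la = (fp - fm) / (2 * h_alpha)
        n_eval += 3
        grad = np.empty_like(theta)
        grad[:nz_ex] = (ex * (g_ex - float(g_ex @ ex)))[:nz_ex]
        if est_comp:
            grad[nz_ex : nz_ex + nz_comp] = (comp * (g_comp - float(g_comp @ comp)))[:nz_comp]
        grad[-1] = g_la
        if not np.isfinite(f):
            return 1e300, np.zeros_like(theta)
        return -f, -grad

    def pack_init(model: SubstitutionModel) -> np.ndarray:
        parts = [_logits(model.exchangeabilities)[:nz_ex]]
        if est_comp:
            parts.append(_logits(model.composition)[:nz_comp])
        parts.append([math.log(min(max(model.alpha, _ALPHA_MIN), _ALPHA_MAX))])
        return np.concatenate(parts)

    attempts = [init]
    if init.name != "Poisson":
        fallback = poisson_model(alpha=1.0, ncat=ncat)
        fb_comp = fixed_comp if fixed_comp is not None else empirical_frequencies(pats)
        attempts.append(SubstitutionModel(fallback.exchangeabilities, fb_comp, alpha=1.0, ncat=ncat))

    last_exc: Exception | None = None
    for attempt, start in enumerate(attempts):
        theta0 = pack_init(start)
        f0, _ = objective(theta0)
        if not np.isfinite(f0):
            last_exc = ValueError("non-finite log-likelihood at initialisation")
            continue
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-5, "maxcor": 20},
        )
        if np.isfinite(res.fun):
            ex, comp, alpha = unpack(res.x)
            model = SubstitutionModel(ex, comp, alpha=alpha, ncat=ncat, name=f"ml_F{freq_mode.value}")
            return EstimationResult(
                model=model,
                log_likelihood=float(-res.fun),
                n_evaluations=n_eval,
                n_iterations=int(res.nit),
                converged=bool(res.success),
                settings={
                    "freq_mode": freq_mode.value,
                    "maxiter": maxiter,
                    "ftol": ftol,
                    "restarts": attempt,
                },
            )
        last_exc = ValueError("optimizer returned non-finite objective")
    raise last_exc or RuntimeError("estimation failed")


# ---------------------------------------------------------------------------
# Bayesian estimation
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Schedule and proposal settings for the Metropolis-Hastings sampler.

    Defaults mirror the long-run protocol: 600,000 generations sampled every
    100 generations (6,000 samples), the first 1,000 samples discarded as
    burn-in, leaving 5,000 for the posterior summary.
    """

    generations: int = 600_000
    sample_interval: int = 100
    burnin_samples: int = 1_000
    seed: int = 0
    ex_concentration: float = 3000.0
    comp_concentration: float = 500.0
    alpha_window: float = 0.2

    def __post_init__(self):
        if self.generations % self.sample_interval != 0:
            raise ValueError("generations must be divisible by sample_interval")
        if self.burnin_samples >= self.generations // self.sample_interval:
            raise ValueError("burn-in discards every sample")

    @property
    def n_samples(self) -> int:
        return self.generations // self.sample_interval


@dataclass
class MCMCTrace:
    exchangeabilities: np.ndarray  # (n_samples, 190)
    compositions: np.ndarray  # (n_samples, 20)
    alphas: np.ndarray  # (n_samples,)
    log_posteriors: np.ndarray  # (n_samples,)
    acceptance_rates: dict
    warnings: list


def _dirichlet_logpdf(x: np.ndarray, a: np.ndarray) -> float:
    return float(gammaln(a.sum()) - gammaln(a).sum() + ((a - 1.0) * np.log(x)).sum())


def estimate_bayes(
    aln: Alignment | SitePatterns,
    tree: PhyloTree,
    config: MCMCConfig | None = None,
    ncat: int = 4,
) -> tuple[SubstitutionModel, MCMCTrace]:
    """Bayesian GTR20+Gamma estimation on a fixed tree.

    One Metropolis-Hastings kernel fires per generation (exchangeabilities,
    composition, alpha, in rotation).  Proposal concentrations are auto-tuned
    toward 20-50% acceptance during the first 10% of generations (inside the
    burn-in) and frozen afterwards.
    """
    config = config or MCMCConfig()
    pats = compress_patterns(aln) if isinstance(aln, Alignment) else aln
    engine = PruningEngine(tree, pats)
    rng = np.random.default_rng(config.seed)

    floor = 1e-8
    ex = np.full(N_PAIRS, 1.0 / N_PAIRS)
    comp = empirical_frequencies(pats)
    alpha = 1.0

    def log_post(ex_, comp_, alpha_):
        engine.set_parameters(ex_, comp_, alpha_, ncat)
        return engine.log_likelihood() - alpha_  # flat Dirichlet priors; Exp(1) on alpha

    lp = log_post(ex, comp, alpha)

    kappa_ex = config.ex_concentration
    kappa_comp = config.comp_concentration
    window = config.alpha_window
    tune_until = config.generations // 10
    tune_block = max(tune_until // 20, 1)

    props = {"ex": 0, "comp": 0, "alpha": 0}
    accs = {"ex": 0, "comp": 0, "alpha": 0}
    block_props = {"ex": 0, "comp": 0, "alpha": 0}
    block_accs = {"ex": 0, "comp": 0, "alpha": 0}

    n_samples = config.n_samples
    tr_ex = np.empty((n_samples, N_PAIRS))
    tr_comp = np.empty((n_samples, N_STATES))
    tr_alpha = np.empty(n_samples)
    tr_lp = np.empty(n_samples)

    kinds = ("ex", "comp", "alpha")
    for gen in range(1, config.generations + 1):
        kind = kinds[(gen - 1) % 3]
        if kind == "ex":
            a_fwd = np.maximum(kappa_ex * ex, 0.05)
            prop = rng.dirichlet(a_fwd)
            prop = np.maximum(prop, floor)
            prop /= prop.sum()
            a_rev = np.maximum(kappa_ex * prop, 0.05)
            log_h = _dirichlet_logpdf(ex, a_rev) - _dirichlet_logpdf(prop, a_fwd)
            lp_new = log_post(prop, comp, alpha)
            if math.log(rng.random()) < lp_new - lp + log_h:
                ex, lp = prop, lp_new
                accs[kind] += 1
                block_accs[kind] += 1
        elif kind == "comp":
            a_fwd = np.maximum(kappa_comp * comp, 0.05)
            prop = rng.dirichlet(a_fwd)
            prop = np.maximum(prop, floor)
            prop /= prop.sum()
            a_rev = np.maximum(kappa_comp * prop, 0.05)
            log_h = _dirichlet_logpdf(comp, a_rev) - _dirichlet_logpdf(prop, a_fwd)
            lp_new = log_post(ex, prop, alpha)
            if math.log(rng.random()) < lp_new - lp + log_h:
                comp, lp = prop, lp_new
                accs[kind] += 1
                block_accs[kind] += 1
        else:
            prop_alpha = alpha * math.exp(window * (rng.random() - 0.5))
            if _ALPHA_MIN < prop_alpha < _ALPHA_MAX:
                log_h = math.log(prop_alpha / alpha)
                lp_new = log_post(ex, comp, prop_alpha)
                if math.log(rng.random()) < lp_new - lp + log_h:
                    alpha, lp = prop_alpha, lp_new
                    accs[kind] += 1
                    block_accs[kind] += 1
        props[kind] += 1
        block_props[kind] += 1

        if gen <= tune_until and gen % tune_block == 0:
            for k, adj in (("ex", "kappa"), ("comp", "kappa"), ("alpha", "window")):
                if block_props[k] == 0:
                    continue
                rate = block_accs[k] / block_props[k]
                if adj == "kappa":
                    if rate < 0.20:
                        factor = 2.0
                    elif rate > 0.50:
                        factor = 0.5
                    else:
                        factor = 1.0
                    if k == "ex":
                        kappa_ex = min(max(kappa_ex * factor, 50.0), 1e7)
                    else:
                        kappa_comp = min(max(kappa_comp * factor, 20.0), 1e7)
                else:
                    if rate < 0.20:
                        window = max(window * 0.5, 1e-3)
                    elif rate > 0.50:
                        window = min(window * 2.0, 5.0)
                block_props[k] = 0
                block_accs[k] = 0

        if gen % config.sample_interval == 0:
            s = gen // config.sample_interval - 1
            tr_ex[s] = ex
            tr_comp[s] = comp
            tr_alpha[s] = alpha
            tr_lp[s] = lp

    rates = {k: (accs[k] / props[k] if props[k] else 0.0) for k in kinds}
    warnings = [
        f"{k} kernel acceptance rate {rates[k]:.3f} outside [0.01, 0.99]"
        for k in kinds
        if props[k] and not (0.01 <= rates[k] <= 0.99)
    ]
    for w in warnings:
        logger.warning(w)

    post = slice(config.burnin_samples, None)
    mean_ex = tr_ex[post].mean(axis=0)
    mean_ex /= mean_ex.sum()
    mean_comp = tr_comp[post].mean(axis=0)
    mean_comp /= mean_comp.sum()
    mean_alpha = float(tr_alpha[post].mean())
    model = SubstitutionModel(mean_ex, mean_comp, alpha=mean_alpha, ncat=ncat, name="bayes")
    trace = MCMCTrace(tr_ex, tr_comp, tr_alpha, tr_lp, rates, warnings)
    return model, trace
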