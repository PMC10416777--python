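"""Reversible 20-state substitution models and rate-matrix mathematics.

A general time-reversible (GTR) amino-acid model is parameterised by 190
symmetric exchangeabilities r_ij (one per unordered residue pair; 189 free
once confined to the unit simplex), 20 stationary frequencies pi_i, and a
discrete-gamma distribution of among-site rate variation with shape alpha
and (by default) four equal-probability categories.  The instantaneous rate
matrix has off-diagonal entries q_ij = r_ij * pi_j and is rescaled so the
mean rate -sum_i pi_i q_ii equals 1, making branch lengths expected numbers
of substitutions per site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alphabet import (
    AMINO_ACIDS,
    N_PAIRS,
    N_STATES,
    matrix_to_pairs,
    pairs_to_matrix,
)

logger = logging.getLogger(__name__)

_FREQ_FLOOR = 1e-10


class DegenerateModelError(ValueError):
    """Raised when a model cannot define an irreducible Markov chain."""


def normalize_exchangeabilities(values: np.ndarray) -> np.ndarray:
    """Project a nonnegative 190-vector of exchangeabilities onto the unit
    simplex (divide by the total).  Scale-invariant by construction."""
    values = np.asarray(values, dtype=float)
    if values.shape != (N_PAIRS,):
        raise ValueError(f"expected {N_PAIRS} exchangeabilities, got {values.shape}")
    if np.any(values < 0):
        raise ValueError("exchangeabilities must be nonnegative")
    total = values.sum()
    if total <= 0:
        raise DegenerateModelError("all exchangeabilities are zero")
    return values / total


def validate_composition(freqs: np.ndarray, *, floor_zeros: bool = False) -> np.ndarray:
    """Check (and optionally repair) a stationary composition vector."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (N_STATES,):
        raise ValueError(f"expected {N_STATES} frequencies, got {freqs.shape}")
    if np.any(freqs < 0):
        raise ValueError("frequencies must be nonnegative")
    total = freqs.sum()
    if abs(total - 1.0) > 1e-3:
        raise ValueError(f"frequencies sum to {total:.6f}, expected ~1")
    freqs = freqs / total
    if np.any(freqs == 0):
        if not floor_zeros:
            raise DegenerateModelError("zero stationary frequency (model not irreducible)")
        logger.warning("flooring %d zero frequencies at %g", int((freqs == 0).sum()), _FREQ_FLOOR)
        freqs = np.maximum(freqs, _FREQ_FLOOR)
        freqs = freqs / freqs.sum()
    return freqs


@dataclass(frozen=True)
class GammaRateModel:
    """Discrete-gamma among-site rate variation (equal-probability bins)."""

    alpha: float
    ncat: int
    rates: np.ndarray
    weights: np.ndarray


def discretize_gamma(alpha: float, ncat: int = 4) -> GammaRateModel:
    """Discretise a gamma(alpha, alpha) rate distribution into ``ncat``
    equal-probability categories, each represented by its conditional mean.

    The mean of gamma(a, a) over the quantile interval [q_{k}, q_{k+1}] is
    ncat * [I(a+1, a*q_{k+1}) - I(a+1, a*q_k)] where I is the regularised
    lower incomplete gamma function, so the weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return GammaRateModel(alpha, 1, np.ones(1), np.ones(1))
    probs = np.arange(1, ncat) / ncat
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1.0, alpha * bounds[1:]))
    lower = gammainc(alpha + 1.0, alpha * np.where(np.isinf(bounds[:-1]), 0.0, bounds[:-1]))
    rates = ncat * (upper - lower)
    rates = rates / (rates.mean())  # exact mean-1 against roundoff
    weights = np.full(ncat, 1.0 / ncat)
    return GammaRateModel(float(alpha), int(ncat), rates, weights)


@dataclass(frozen=True)
class SubstitutionModel:
    """A fully specified GTR20+Gamma model.

    exchangeabilities: 190-vector on the unit simplex (lower-triangle order)
    composition: 20 stationary frequencies summing to 1
    alpha: gamma shape; ncat: number of discrete rate categories
    """

    exchangeabilities: np.ndarray
    composition: np.ndarray
    alpha: float = 1.0
    ncat: int = 4
    name: str = "unnamed"
    gamma: GammaRateModel = field(init=False, repr=False)

    def __post_init__(self):
        ex = normalize_exchangeabilities(self.exchangeabilities)
        comp = validate_composition(self.composition)
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "composition", comp)
        object.__setattr__(self, "gamma", discretize_gamma(self.alpha, self.ncat))

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return replace(self, alpha=float(alpha))

    def with_composition(self, comp: np.ndarray) -> "SubstitutionModel":
        return replace(self, composition=np.asarray(comp, dtype=float))

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self.exchangeabilities, self.composition)


def poisson_model(alpha: float = 1.0, ncat: int = 4) -> SubstitutionModel:
    """The Poisson (equal-rates, equal-frequencies) model."""
    return SubstitutionModel(
        exchangeabilities=np.full(N_PAIRS, 1.0 / N_PAIRS),
        composition=np.full(N_STATES, 1.0 / N_STATES),
        alpha=alpha,
        ncat=ncat,
        name="Poisson",
    )


def build_rate_matrix(exchangeabilities: np.ndarray, composition: np.ndarray) -> np.ndarray:
    """Build the scaled instantaneous rate matrix Q.

    q_ij = r_ij * pi_j for i != j, diagonals make rows sum to zero, and the
    whole matrix is rescaled so that -sum_i pi_i q_ii = 1.
    """
    ex = normalize_exchangeabilities(exchangeabilities)
    comp = validate_composition(composition)
    if np.any(comp <= 0):
        raise DegenerateModelError("zero stationary frequency (model not irreducible)")
    r = pairs_to_matrix(ex)
    q = r * comp[None, :]
    np.fill_diagonal(q, 0.0)
    q[np.diag_indices_from(q)] = -q.sum(axis=1)
    mean_rate = -np.dot(comp, np.diag(q))
    if mean_rate <= 0:
        raise DegenerateModelError("degenerate model: zero mean substitution rate")
    return q / mean_rate


@dataclass(frozen=True)
class ModelEigensystem:
    """Spectral decomposition of the symmetrised rate matrix.

    B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric for a reversible Q;
    with B = V diag(lam) V^T, P(t) = diag(1/sqrt(pi)) V exp(lam t) V^T diag(sqrt(pi)).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # V, orthonormal columns
    sqrt_pi: np.ndarray
    inv_sqrt_pi: np.ndarray
    composition: np.ndarray

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        v = self.eigenvectors
        expd = np.exp(self.eigenvalues * t)
        p = (self.inv_sqrt_pi[:, None] * v) @ (expd[:, None] * (v.T * self.sqrt_pi[None, :]))
        np.clip(p, 0.0, 1.0, out=p)
        # renormalise tiny clipping residue so rows sum to exactly 1
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of scaled times, shape (len(ts), 20, 20)."""
        v = self.eigenvectors
        expd = np.exp(np.multiply.outer(np.asarray(ts, dtype=float), self.eigenvalues))
        left = self.inv_sqrt_pi[:, None] * v
        right = v.T * self.sqrt_pi[None, :]
        p = np.matmul(left[None, :, :] * expd[:, None, :], right)
        np.clip(p, 0.0, 1.0, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def decompose_model(exchangeabilities: np.ndarray, composition: np.ndarray) -> ModelEigensystem:
    q = build_rate_matrix(exchangeabilities, composition)
    comp = validate_composition(composition)
    sqrt_pi = np.sqrt(comp)
    inv_sqrt_pi = 1.0 / sqrt_pi
    b = sqrt_pi[:, None] * q * inv_sqrt_pi[None, :]
    b = 0.5 * (b + b.T)  # enforce exact symmetry against roundoff
    lam, v = np.linalg.eigh(b)
    return ModelEigensystem(lam, v, sqrt_pi, inv_sqrt_pi, comp)


def transition_probabilities(q: np.ndarray, composition: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible Q, via the symmetric eigenroute."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    comp = validate_composition(composition)
    sqrt_pi = np.sqrt(comp)
    b = sqrt_pi[:, None] * np.asarray(q, dtype=float) / sqrt_pi[None, :]
    b = 0.5 * (b + b.T)
    lam, v = np.linalg.eigh(b)
    expd = np.exp(lam * t)
    p = (v / sqrt_pi[:, None]) @ (expd[:, None] * (v.T * sqrt_pi[None, :]))
    np.clip(p, 0.0, 1.0, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# PAML-style "dat" model files: 19 lower-triangular exchangeability rows
# followed by 20 stationary frequencies, whitespace-flexible.
# ---------------------------------------------------------------------------

def read_model_file(path, alpha: float = 1.0, ncat: int = 4, name: str | None = None) -> SubstitutionModel:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    rows: list[list[float]] = []
    for ln in lines:
        try:
            rows.append([float(tok) for tok in ln.split()])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric token in line {ln!r}") from exc
    if len(rows) < 20:
        raise ValueError(f"{path}: expected 19 exchangeability rows plus frequencies, got {len(rows)} rows")
    ex = np.empty(N_PAIRS)
    pos = 0
    for i in range(1, N_STATES):
        row = rows[i - 1]
        if len(row) != i:
            raise ValueError(
                f"{path}: exchangeability row {i} has {len(row)} entries, expected {i}"
            )
        ex[pos : pos + i] = row
        pos += i
    freqs = [x for row in rows[19:] for x in row]
    if len(freqs) != N_STATES:
        raise ValueError(f"{path}: expected 20 frequencies, got {len(freqs)}")
    ex = np.asarray(ex)
    if np.any(ex < 0):
        raise ValueError(f"{path}: negative exchangeability rate")
    freqs = np.asarray(freqs, dtype=float)
    total = freqs.sum()
    if abs(total - 1.0) > 1e-3:
        raise ValueError(f"{path}: frequencies sum to {total:.6f}, expected ~1")
    freqs = validate_composition(freqs / total, floor_zeros=True)
    import os

    return SubstitutionModel(
        exchangeabilities=normalize_exchangeabilities(ex),
        composition=freqs,
        alpha=alpha,
        ncat=ncat,
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
    )


def write_model_file(model: SubstitutionModel, path) -> None:
    r = pairs_to_matrix(model.exchangeabilities)
    with open(path, "w") as fh:
        for i in range(1, N_STATES):
            fh.write(" ".join(f"{r[i, j]:.12g}" for j in range(i)) + "\n")
        fh.write("\n")
        fh.write(" ".join(f"{f:.12g}" for f in model.composition) + "\n")


def bundled_model_path(stem: str):
    """Path to a model file shipped with the package (e.g. 'poisson')."""
    from importlib.resources import files

    return files("aamodelkit.data").joinpath(f"{stem}.dat")
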