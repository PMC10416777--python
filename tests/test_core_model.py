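"""Rate-matrix construction, transition probabilities, gamma discretisation,
and model-file round trips."""

import numpy as np
import pytest
import scipy.integrate
import scipy.linalg
import scipy.stats

from aamodelkit import (
    build_rate_matrix,
    discretize_gamma,
    normalize_exchangeabilities,
    poisson_model,
    random_model,
    read_model_file,
    transition_probabilities,
    write_model_file,
)
from aamodelkit.alphabet import N_PAIRS, N_STATES
from aamodelkit.model import DegenerateModelError, bundled_model_path, decompose_model


class TestBuildRateMatrix:
    def test_uniform_model_is_symmetric_poisson(self):
        q = build_rate_matrix(np.full(N_PAIRS, 1.0), np.full(N_STATES, 1 / 20))
        off = q[~np.eye(N_STATES, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(np.diag(q), -19 * off[0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_models_satisfy_rate_matrix_contract(self, seed):
        m = random_model(seed)
        q = build_rate_matrix(m.exchangeabilities, m.composition)
        pi = m.composition
        # rows sum to zero
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)
        # detailed balance pi_i q_ij = pi_j q_ji over all 380 ordered pairs
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-10)
        # mean rate scaled to exactly 1
        assert abs(-np.dot(pi, np.diag(q)) - 1.0) < 1e-10
        assert np.all(q[~np.eye(N_STATES, dtype=bool)] >= 0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateModelError):
            build_rate_matrix(np.zeros(N_PAIRS), np.full(N_STATES, 1 / 20))
        comp = np.full(N_STATES, 1 / 19)
        comp[0] = 0.0
        comp /= comp.sum()
        with pytest.raises(DegenerateModelError):
            build_rate_matrix(np.full(N_PAIRS, 1.0), comp)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, small_model):
        q = small_model.rate_matrix()
        p = transition_probabilities(q, small_model.composition, 0.0)
        assert np.allclose(p, np.eye(N_STATES), atol=1e-12)

    def test_negative_time_rejected(self, small_model):
        with pytest.raises(ValueError):
            transition_probabilities(small_model.rate_matrix(), small_model.composition, -0.1)

    @pytest.mark.parametrize("t", [0.05, 0.5, 2.0])
    def test_poisson_closed_form(self, t):
        """Equal-rates chain: p_ii(t) = 1/20 + (19/20) exp(-20 t / 19)."""
        m = poisson_model()
        p = transition_probabilities(m.rate_matrix(), m.composition, t)
        expected_ii = 1 / 20 + (19 / 20) * np.exp(-(20 / 19) * t)
        assert np.allclose(np.diag(p), expected_ii, atol=1e-10)
        expected_ij = (1 - expected_ii) / 19
        assert np.allclose(p[~np.eye(N_STATES, dtype=bool)], expected_ij, atol=1e-10)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_agrees_with_scipy_expm(self, seed, t):
        m = random_model(seed)
        q = m.rate_matrix()
        p = transition_probabilities(q, m.composition, t)
        oracle = scipy.linalg.expm(q * t)
        assert np.allclose(p, oracle, atol=1e-9)

    def test_rows_are_distributions_and_converge_to_composition(self, small_model):
        q = small_model.rate_matrix()
        for t in (0.1, 1.0, 5.0):
            p = transition_probabilities(q, small_model.composition, t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert p.min() >= 0.0 and p.max() <= 1.0
        p_inf = transition_probabilities(q, small_model.composition, 50.0)
        assert np.allclose(p_inf, np.tile(small_model.composition, (N_STATES, 1)), atol=1e-6)

    def test_chapman_kolmogorov(self, small_model):
        q = small_model.rate_matrix()
        pi = small_model.composition
        p_s = transition_probabilities(q, pi, 0.1)
        p_t = transition_probabilities(q, pi, 0.3)
        p_st = transition_probabilities(q, pi, 0.4)
        assert np.allclose(p_s @ p_t, p_st, atol=1e-9)


class TestDiscretizeGamma:
    @pytest.mark.parametrize("alpha,ncat", [(0.2, 4), (1.0, 4), (5.0, 8), (0.7, 1)])
    def test_mean_rate_is_one(self, alpha, ncat):
        g = discretize_gamma(alpha, ncat)
        assert abs(np.dot(g.weights, g.rates) - 1.0) < 1e-10
        assert np.allclose(g.weights, 1.0 / ncat)

    def test_huge_alpha_removes_heterogeneity(self):
        g = discretize_gamma(1e6, 4)
        assert np.allclose(g.rates, 1.0, atol=1e-2)

    def test_category_means_match_quadrature(self):
        """Category rates equal the conditional means of gamma(a, a) over the
        equal-probability quantile bins (adaptive-quadrature oracle)."""
        alpha, ncat = 0.5, 4
        g = discretize_gamma(alpha, ncat)
        dist = scipy.stats.gamma(a=alpha, scale=1 / alpha)
        cuts = [0.0] + [dist.ppf(k / ncat) for k in range(1, ncat)] + [np.inf]
        for k in range(ncat):
            mean_k, _ = scipy.integrate.quad(lambda x: x * dist.pdf(x), cuts[k], cuts[k + 1])
            assert abs(g.rates[k] - ncat * mean_k) < 1e-8

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 3.0, 20.0])
    def test_rates_strictly_increase(self, alpha):
        g = discretize_gamma(alpha, 6)
        assert np.all(np.diff(g.rates) > 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)
        with pytest.raises(ValueError):
            discretize_gamma(1.0, 0)


class TestNormalizeExchangeabilities:
    def test_idempotent_and_scale_invariant(self, rng):
        v = rng.gamma(0.5, size=N_PAIRS)
        n1 = normalize_exchangeabilities(v)
        assert abs(n1.sum() - 1.0) < 1e-12
        assert np.allclose(normalize_exchangeabilities(n1), n1)
        assert np.allclose(normalize_exchangeabilities(7.3 * v), n1)

    def test_uniform_input(self):
        assert np.allclose(normalize_exchangeabilities(np.full(N_PAIRS, 3.0)), 1.0 / N_PAIRS)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateModelError):
            normalize_exchangeabilities(np.zeros(N_PAIRS))


class TestModelFiles:
    def test_round_trip(self, tmp_path, rng):
        m = random_model(55)
        path = tmp_path / "model.dat"
        write_model_file(m, path)
        back = read_model_file(path, alpha=m.alpha)
        assert np.allclose(back.exchangeabilities, m.exchangeabilities, atol=1e-10)
        assert np.allclose(back.composition, m.composition, atol=1e-10)

    def test_bundled_poisson_is_uniform(self):
        m = read_model_file(bundled_model_path("poisson"))
        assert np.allclose(m.exchangeabilities, 1.0 / N_PAIRS)
        assert np.allclose(m.composition, 1.0 / N_STATES)

    def test_malformed_row_names_offender(self, tmp_path):
        path = tmp_path / "bad.dat"
        m = random_model(58)
        write_model_file(m, path)
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        lines[1] = "0.2 0.3 0.9"  # row 2 must have exactly 2 entries
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 2"):
            read_model_file(path)

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "short.dat"
        path.write_text("0.1\n0.2 0.3\n0.4 0.5 0.6\n")
        with pytest.raises(ValueError, match="rows"):
            read_model_file(path)

    def test_negative_rate_rejected(self, tmp_path):
        m = random_model(56)
        path = tmp_path / "neg.dat"
        write_model_file(m, path)
        lines = path.read_text().splitlines()
        lines[0] = "-0.5"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="negative"):
            read_model_file(path)

    def test_bad_frequency_sum_rejected(self, tmp_path):
        m = random_model(57)
        path = tmp_path / "badfreq.dat"
        write_model_file(m, path)
        lines = path.read_text().splitlines()
        lines[-1] = " ".join(["0.1"] * 20)  # sums to 2
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="frequencies sum"):
            read_model_file(path)


def test_eigensystem_matches_expm_on_category_scaled_times(small_model):
    eig = decompose_model(small_model.exchangeabilities, small_model.composition)
    q = small_model.rate_matrix()
    ts = small_model.gamma.rates * 0.37
    stack = eig.transition_matrices(ts)
    for k, t in enumerate(ts):
        assert np.allclose(stack[k], scipy.linalg.expm(q * t), atol=1e-9)
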