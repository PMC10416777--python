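"""Pruning likelihood: oracle equivalence, pulley principle, pattern
compression, missing data, and analytic-gradient consistency."""

import numpy as np
import pytest

from aamodelkit import (
    Alignment,
    brute_force_log_likelihood,
    compress_patterns,
    log_likelihood,
    poisson_model,
    random_model,
    random_tree,
    simulate_alignment,
)
from aamodelkit.likelihood import PruningEngine, SitePatterns
from aamodelkit.trees import PhyloTree


class TestCompressPatterns:
    def test_constant_alignment_single_pattern(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "AAAA", "AAAA"])
        pats = compress_patterns(aln)
        assert pats.patterns.shape[1] == 1
        assert pats.weights.tolist() == [4.0]

    def test_weights_sum_to_length(self):
        aln = Alignment(["a", "b"], ["ARNA", "ARRA"])
        pats = compress_patterns(aln)
        assert pats.patterns.shape[1] == 3
        assert pats.weights.sum() == 4

    def test_expansion_recovers_column_multiset(self, rng):
        from aamodelkit.alphabet import AMINO_ACIDS

        cols = rng.integers(0, 20, size=(5, 60))
        seqs = ["".join(AMINO_ACIDS[c] for c in row) for row in cols]
        aln = Alignment([f"s{i}" for i in range(5)], seqs)
        pats = compress_patterns(aln)
        expanded = []
        for k in range(pats.patterns.shape[1]):
            expanded += [tuple(pats.patterns[:, k])] * int(pats.weights[k])
        assert sorted(expanded) == sorted(map(tuple, cols.T))

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment(["a", "b"], ["AR", "A"])


class TestLogLikelihoodClosedForms:
    def test_two_identical_residues_zero_branch(self):
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        aln = Alignment(["A", "B"], ["A", "A"])
        m = poisson_model(ncat=1)
        assert log_likelihood(tree, m, aln) == pytest.approx(np.log(1 / 20), abs=1e-12)

    def test_saturation_factorises_into_stationary_frequencies(self, small_model):
        from aamodelkit.model import SubstitutionModel

        m = SubstitutionModel(small_model.exchangeabilities, small_model.composition, alpha=1.0, ncat=1)
        tree = PhyloTree.from_newick("(A:100.0,B:100.0);")
        aln = Alignment(["A", "B"], ["A", "R"])
        pi = m.composition
        expected = np.log(pi[0] * pi[1])
        assert log_likelihood(tree, m, aln) == pytest.approx(expected, abs=1e-6)

    def test_label_mismatch_lists_difference(self, small_model):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2,C:0.1);")
        aln = Alignment(["A", "B", "D"], ["A", "R", "N"])
        with pytest.raises(ValueError, match="D"):
            log_likelihood(tree, small_model, aln)


class TestBruteForceOracle:
    @pytest.mark.parametrize("ntaxa,nsites,seed", [(4, 3, 0), (4, 5, 1), (5, 2, 2), (6, 2, 3)])
    def test_pruning_matches_exhaustive_marginalisation(self, ntaxa, nsites, seed):
        m = random_model(seed, concentration=1.5)
        tree = random_tree(ntaxa, 1.5, seed=seed)
        aln = simulate_alignment(tree, m, nsites, seed=seed + 100)
        assert log_likelihood(tree, m, aln) == pytest.approx(
            brute_force_log_likelihood(tree, m, aln), abs=1e-10
        )

    def test_two_taxon_case(self, small_model):
        tree = PhyloTree.from_newick("(A:0.3,B:0.2);")
        aln = Alignment(["A", "B"], ["ARN", "ARD"])
        assert log_likelihood(tree, small_model, aln) == pytest.approx(
            brute_force_log_likelihood(tree, small_model, aln), abs=1e-12
        )

    def test_refuses_large_trees(self, small_model):
        tree = random_tree(10, 2.0, seed=4)
        aln = simulate_alignment(tree, small_model, 2, seed=5)
        with pytest.raises(ValueError, match="internal nodes"):
            brute_force_log_likelihood(tree, small_model, aln)


class TestPulleyPrinciple:
    def test_rerooting_preserves_likelihood(self, small_model):
        tree = random_tree(8, 2.2, seed=6)
        aln = simulate_alignment(tree, small_model, 120, seed=7)
        base = log_likelihood(tree, small_model, aln)
        for edge in tree.edges():
            for frac in (0.25, 0.5):
                rerooted = tree.reroot_at_edge(edge, frac)
                assert log_likelihood(rerooted, small_model, aln) == pytest.approx(base, abs=1e-9)


class TestPatternAndMissingContracts:
    def test_compression_invariance(self, small_model, six_taxon_case):
        tree, aln = six_taxon_case
        pats = compress_patterns(aln)
        uncompressed = SitePatterns(
            list(aln.labels), aln.codes(), np.ones(aln.n_sites)
        )
        e1 = PruningEngine(tree, pats)
        e2 = PruningEngine(tree, uncompressed)
        e1.set_model(small_model)
        e2.set_model(small_model)
        assert e1.log_likelihood() == pytest.approx(e2.log_likelihood(), abs=1e-10)

    def test_all_missing_column_contributes_zero(self, small_model, six_taxon_case):
        tree, aln = six_taxon_case
        base = log_likelihood(tree, small_model, aln)
        padded = Alignment(list(aln.labels), [s + "X-?" for s in aln.sequences])
        assert log_likelihood(tree, small_model, padded) == pytest.approx(base, abs=1e-10)

    def test_per_site_logl_stabilises_with_length(self, small_model):
        tree = random_tree(6, 1.8, seed=8)
        a8 = simulate_alignment(tree, small_model, 8000, seed=9)
        a4 = Alignment(list(a8.labels), [s[:4000] for s in a8.sequences])
        per8 = log_likelihood(tree, small_model, a8) / 8000
        per4 = log_likelihood(tree, small_model, a4) / 4000
        assert abs(per8 - per4) < 0.05


class TestAnalyticGradient:
    def test_gradient_matches_central_finite_differences(self):
        """The backward-pass exchangeability and composition gradients agree
        with central finite differences at step 1e-6."""
        m = random_model(31, concentration=2.0, alpha=0.7)
        tree = random_tree(7, 2.0, seed=32)
        aln = simulate_alignment(tree, m, 80, seed=33)
        engine = PruningEngine(tree, aln)
        engine.set_model(m)
        f0, g_ex, g_comp = engine.log_likelihood_and_gradient()
        assert f0 == pytest.approx(engine.log_likelihood(), abs=1e-12)
        h = 1e-6
        rng = np.random.default_rng(0)
        for k in rng.choice(190, size=8, replace=False):
            for arr, grad, nparam in ((m.exchangeabilities, g_ex, 190),):
                v = arr.copy()
                v[k] += h
                engine.set_parameters(v, m.composition, m.alpha)
                fp = engine.log_likelihood()
                v[k] -= 2 * h
                engine.set_parameters(v, m.composition, m.alpha)
                fm = engine.log_likelihood()
                assert (fp - fm) / (2 * h) == pytest.approx(grad[k], abs=1e-4, rel=1e-4)
        for k in range(0, 20, 5):
            v = m.composition.copy()
            v[k] += h
            engine.set_parameters(m.exchangeabilities, v, m.alpha)
            fp = engine.log_likelihood()
            v[k] -= 2 * h
            engine.set_parameters(m.exchangeabilities, v, m.alpha)
            fm = engine.log_likelihood()
            assert (fp - fm) / (2 * h) == pytest.approx(g_comp[k], abs=1e-4, rel=1e-4)

    def test_gradient_orthogonal_to_exchangeability_scaling(self, six_taxon_case, small_model):
        """logL is invariant to rescaling all exchangeabilities, so the
        gradient must be orthogonal to the current parameter vector."""
        tree, aln = six_taxon_case
        engine = PruningEngine(tree, aln)
        engine.set_model(small_model)
        _, g_ex, _ = engine.log_likelihood_and_gradient()
        assert abs(float(g_ex @ small_model.exchangeabilities)) < 1e-8
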