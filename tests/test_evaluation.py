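"""Tree distances, PCA ordination, and the two-group test battery."""

import itertools

import dendropy
import numpy as np
import pytest
import scipy.stats

from aamodelkit import poisson_model, random_model, random_tree
from aamodelkit.evaluation import (
    compare_groups,
    nrf,
    pca_ordination,
    rf_distance,
    rf_max,
    tree_length,
    wrf_distance,
)
from aamodelkit.trees import PhyloTree


def caterpillar(labels, internal=0.1, pendant=0.05):
    """Ladder tree over the given leaf order."""
    newick = labels[0] + f":{pendant}"
    for lbl in labels[1:-1]:
        newick = f"({newick},{lbl}:{pendant}):{internal}"
    newick = f"({newick},{labels[-1]}:{pendant});"
    return PhyloTree.from_newick(newick)


def interleaved_pair(n):
    """Two caterpillars with no shared nontrivial bipartition."""
    labels = [f"t{i}" for i in range(n)]
    a = caterpillar(labels)
    order = labels[0::2] + labels[1::2]
    b = caterpillar(order)
    return a, b


class TestRfDistance:
    def test_identical_topologies_different_lengths(self):
        a = PhyloTree.from_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.5):0.6,E:0.1);")
        b = PhyloTree.from_newick("((A:1.1,B:2.2):1.3,(C:1.4,D:1.5):1.6,E:1.1);")
        assert rf_distance(a, b) == 0
        assert nrf(a, b) == 0.0

    def test_four_taxon_alternative_splits(self):
        a = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        b = PhyloTree.from_newick("((A:0.1,C:0.1):0.1,B:0.1,D:0.1);")
        assert rf_distance(a, b) == 2

    @pytest.mark.parametrize("n", [6, 10, 26])
    def test_maximally_different_caterpillars(self, n):
        a, b = interleaved_pair(n)
        assert rf_distance(a, b) == rf_max(n) == 2 * (n - 3)
        assert nrf(a, b) == 1.0

    def test_leafset_mismatch_raises(self):
        a = PhyloTree.from_newick("(A:1,B:1,C:1);")
        b = PhyloTree.from_newick("(A:1,B:1,D:1);")
        with pytest.raises(ValueError, match="mismatch"):
            rf_distance(a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dendropy_on_random_pairs(self, seed):
        """Independent cross-check against dendropy's bipartition machinery
        on random pairs of up to 8 taxa."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        a = random_tree(n, 1.0, seed=seed * 2 + 1)
        b = random_tree(n, 1.0, seed=seed * 2 + 2)
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(data=a.to_newick(), schema="newick", taxon_namespace=tns)
        db = dendropy.Tree.get(data=b.to_newick(), schema="newick", taxon_namespace=tns)
        da.encode_bipartitions()
        db.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
        assert rf_distance(a, b) == expected


def _brute_force_wrf(a: PhyloTree, b: PhyloTree) -> float:
    """Oracle: explicit bipartition tables (pendants matched by leaf)."""
    ta = a.bipartitions(include_trivial=True)
    tb = b.bipartitions(include_trivial=True)
    keys = set(ta) | set(tb)
    return sum(abs(ta.get(k, 0.0) - tb.get(k, 0.0)) for k in keys)


class TestWrfDistance:
    def test_identical_trees(self):
        a = random_tree(7, 2.0, seed=1)
        assert wrf_distance(a, a.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_single_pendant_difference(self):
        a = PhyloTree.from_newick("((A:0.1,B:0.2):0.3,C:0.4,D:0.5);")
        b = PhyloTree.from_newick("((A:0.4,B:0.2):0.3,C:0.4,D:0.5);")
        assert wrf_distance(a, b) == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_oracle_agreement(self, seed):
        a = random_tree(8, 2.0, seed=seed + 50)
        b = random_tree(8, 3.0, seed=seed + 80)
        w = wrf_distance(a, b)
        assert w == pytest.approx(wrf_distance(b, a))
        assert w == pytest.approx(_brute_force_wrf(a, b), abs=1e-12)
        assert w >= 0

    def test_unmatched_bipartition_counts_full_length(self):
        a = PhyloTree.from_newick("((A:0.1,B:0.1):0.7,C:0.1,D:0.1);")
        b = PhyloTree.from_newick("((A:0.1,C:0.1):0.2,B:0.1,D:0.1);")
        assert wrf_distance(a, b) == pytest.approx(0.9)


class TestTreeLength:
    def test_sums_branch_lengths(self):
        t = PhyloTree.from_newick("(A:0.1,B:0.2,(C:0.3,D:0.4):0.05);")
        assert tree_length(t) == pytest.approx(1.05)
        assert len(t.edges()) == 5


class TestPcaOrdination:
    def test_two_models_single_axis(self):
        a, b = random_model(1), random_model(2)
        coords, evr, labels = pca_ordination([a, b])
        assert evr[0] == pytest.approx(1.0)
        assert coords.shape[0] == 2

    def test_centroid_model_at_origin(self):
        from aamodelkit.model import SubstitutionModel

        a, b = random_model(3), random_model(4)
        mid = SubstitutionModel(
            0.5 * (a.exchangeabilities + b.exchangeabilities),
            np.full(20, 0.05),
            name="centroid",
        )
        coords, _, _ = pca_ordination([a, b, mid])
        assert np.allclose(coords[2], 0.0, atol=1e-10)

    def test_full_rank_projection_is_isometric(self):
        models = [random_model(s) for s in range(5)]
        vecs = np.vstack([m.exchangeabilities for m in models])
        coords, evr, _ = pca_ordination(models, n_components=4)
        for i, j in itertools.combinations(range(5), 2):
            d_full = np.linalg.norm(vecs[i] - vecs[j])
            d_pc = np.linalg.norm(coords[i] - coords[j])
            assert d_pc == pytest.approx(d_full, rel=1e-9)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-10

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            pca_ordination([random_model(1)])

    def test_grouping_averages_before_projection(self):
        models = [random_model(s) for s in range(4)]
        coords, _, labels = pca_ordination(models, groups=["g1", "g1", "g2", "g3"])
        assert labels == ["g1", "g2", "g3"]
        assert coords.shape[0] == 3


class TestCompareGroups:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        gc = compare_groups(x, x.copy())
        assert gc.test_used == "t"
        assert gc.statistic == pytest.approx(0.0, abs=1e-12)
        assert gc.p_value == pytest.approx(1.0)
        assert gc.delta == pytest.approx(0.0)

    def test_large_shift_detected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        gc = compare_groups(x, x + 100.0)
        assert gc.p_value < 0.001

    def test_pooled_t_formula_oracle(self):
        """The reported t statistic equals the textbook pooled-variance
        formula computed independently."""
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 1.0, 10)
        y = rng.normal(0.5, 1.0, 10)
        gc = compare_groups(x, y)
        assert gc.test_used == "t"
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_manual = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert gc.statistic == pytest.approx(t_manual, abs=1e-10)
        p_manual = 2 * scipy.stats.t.sf(abs(t_manual), nx + ny - 2)
        assert gc.p_value == pytest.approx(p_manual, abs=1e-10)

    def test_wilcoxon_used_when_normality_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1.0, 60) ** 3  # wildly skewed
        y = rng.normal(5.0, 1.0, 60)
        gc = compare_groups(x, y)
        assert min(gc.shapiro_p_x, gc.shapiro_p_y) < 0.05
        assert gc.test_used == "wilcoxon"

    def test_zero_variance_equal_means(self):
        gc = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert gc.p_value == 1.0 and gc.statistic == 0.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_variance_ratio_p_reported(self):
        rng = np.random.default_rng(11)
        gc = compare_groups(rng.normal(0, 1, 30), rng.normal(0, 5, 30))
        assert gc.variance_ratio_p < 0.01


class TestShapiroWilkBehaviour:
    def test_size_calibration_on_normal_samples(self):
        """Rejection rate at alpha=0.05 over 1,000 standard-normal samples of
        size 100 stays near the nominal level."""
        rng = np.random.default_rng(42)
        rejections = sum(
            scipy.stats.shapiro(rng.normal(size=100)).pvalue < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_against_exponential(self):
        rng = np.random.default_rng(43)
        rejections = sum(
            scipy.stats.shapiro(rng.exponential(size=100)).pvalue < 0.05 for _ in range(200)
        )
        assert rejections / 200 > 0.9
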