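"""Model and tree comparison: RF/WRF/nRF distances, tree length, PCA
ordination of normalised exchangeabilities, and the two-group statistical
test battery (Shapiro-Wilk gate, pooled-variance t-test or Wilcoxon
rank-sum, F-test of equal variances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .model import SubstitutionModel, normalize_exchangeabilities
from .trees import PhyloTree


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def _check_leafsets(a: PhyloTree, b: PhyloTree) -> None:
    la, lb = set(a.leaf_labels()), set(b.leaf_labels())
    if la != lb:
        raise ValueError(
            f"leaf-set mismatch: only in first {sorted(la - lb)}, only in second {sorted(lb - la)}"
        )


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson-Foulds distance: the number of nontrivial
    bipartitions present in exactly one of the two (unrooted) trees."""
    _check_leafsets(a, b)
    ba, bb = set(a.bipartitions()), set(b.bipartitions())
    return len(ba ^ bb)


def wrf_distance(a: PhyloTree, b: PhyloTree) -> float:
    """Weighted Robinson-Foulds: sum of |branch length difference| over the
    union of bipartitions, pendant edges included (matched by leaf); a
    bipartition absent from one tree counts its full length."""
    _check_leafsets(a, b)
    ba = a.bipartitions(include_trivial=True)
    bb = b.bipartitions(include_trivial=True)
    total = 0.0
    for key in set(ba) | set(bb):
        total += abs(ba.get(key, 0.0) - bb.get(key, 0.0))
    return float(total)


def rf_max(ntaxa: int) -> int:
    return 2 * (ntaxa - 3)


def nrf(a: PhyloTree, b: PhyloTree) -> float:
    """RF normalised by its maximum 2*(n-3) for unrooted binary trees."""
    _check_leafsets(a, b)
    denom = rf_max(a.n_leaves)
    if denom <= 0:
        return 0.0
    return rf_distance(a, b) / denom


def tree_length(t: PhyloTree) -> float:
    return t.tree_length()


@dataclass
class TreeComparison:
    rf: int
    wrf: float
    nrf: float
    length_a: float
    length_b: float


def compare_trees(a: PhyloTree, b: PhyloTree) -> TreeComparison:
    return TreeComparison(
        rf=rf_distance(a, b),
        wrf=wrf_distance(a, b),
        nrf=nrf(a, b),
        length_a=tree_length(a),
        length_b=tree_length(b),
    )


# ---------------------------------------------------------------------------
# PCA ordination of normalised exchangeabilities
# ---------------------------------------------------------------------------

def pca_ordination(
    models: list[SubstitutionModel],
    groups: list | None = None,
    n_components: int = 2,
):
    """Project models (or group-mean models) onto principal axes of their
    normalised 190-dimensional exchangeability vectors.

    Returns (coordinates, explained_variance_fractions, labels).  When
    ``groups`` is given, vectors sharing a group key are averaged first and
    one point per group is returned.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to ordinate")
    vecs = np.vstack([normalize_exchangeabilities(m.exchangeabilities) for m in models])
    if groups is not None:
        if len(groups) != len(models):
            raise ValueError("groups must align with models")
        keys = list(dict.fromkeys(groups))
        vecs = np.vstack([vecs[[i for i, g in enumerate(groups) if g == k]].mean(axis=0) for k in keys])
        labels = keys
    else:
        labels = [m.name for m in models]
    if np.allclose(vecs, vecs[0]):
        raise ValueError("all models identical: ordination undefined")
    from sklearn.decomposition import PCA

    k = min(n_components, vecs.shape[0] - 1, vecs.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(vecs)
    return coords, pca.explained_variance_ratio_, labels


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    mean_x: float
    mean_y: float
    delta: float  # mean_x - mean_y
    shapiro_p_x: float
    shapiro_p_y: float
    variance_ratio_p: float
    test_used: str  # "t" or "wilcoxon"
    statistic: float
    p_value: float


def compare_groups(x, y, normality_alpha: float = 0.05) -> GroupComparison:
    """Two-sided comparison of two independent replicate sets.

    Shapiro-Wilk is run on each group; if both pass at ``normality_alpha``
    the pooled-variance two-sample t-test is used, otherwise the Wilcoxon
    rank-sum test (normal approximation with tie correction).  The p-value
    of the F-test of equality of variances is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 values")

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        sw_x = sw_y = 0.0  # degenerate: constant samples are non-normal
        if x[0] == y[0]:
            return GroupComparison(
                float(x.mean()), float(y.mean()), 0.0, sw_x, sw_y, 1.0, "t", 0.0, 1.0
            )

    sw_x = float(scipy.stats.shapiro(x).pvalue) if np.ptp(x) > 0 else 0.0
    sw_y = float(scipy.stats.shapiro(y).pvalue) if np.ptp(y) > 0 else 0.0

    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx > 0 and vy > 0:
        f_stat = vx / vy
        dfx, dfy = len(x) - 1, len(y) - 1
        cdf = scipy.stats.f.cdf(f_stat, dfx, dfy)
        var_p = float(2 * min(cdf, 1 - cdf))
    else:
        var_p = 0.0 if vx != vy else 1.0

    if sw_x >= normality_alpha and sw_y >= normality_alpha:
        res = scipy.stats.ttest_ind(x, y, equal_var=True)
        test_used, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        test_used, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)

    return GroupComparison(
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        delta=float(x.mean() - y.mean()),
        shapiro_p_x=sw_x,
        shapiro_p_y=sw_y,
        variance_ratio_p=var_p,
        test_used=test_used,
        statistic=stat,
        p_value=p,
    )
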