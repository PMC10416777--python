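"""Simulation of protein alignments, surrogate trees, and random models.

The study design this emulates: a fixed 26-taxon tree with total length
7.74 expected substitutions per site, alignments of 400 / 1,500 / 8,000
sites evolved under a fixed reversible model with discrete-gamma (4
category) rate variation, 100 replicates per length.  A random root
sequence is drawn from the model composition and evolved along the tree;
each site keeps one gamma-category rate across all branches, matching the
Gamma-mixture likelihood used to score the data.  Child states are sampled
from exact transition matrices per (branch, category) rather than by
event-level simulation.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AMINO_ACIDS, N_PAIRS, N_STATES
from .likelihood import Alignment
from .model import SubstitutionModel, decompose_model, normalize_exchangeabilities
from .trees import Node, PhyloTree


def child_seed(master_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed derived from a master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    nsites: int,
    seed: int | np.random.Generator,
) -> Alignment:
    """Evolve a root sequence over the tree; returns leaf sequences in the
    tree's leaf order.  Deterministic given the seed."""
    if nsites < 1:
        raise ValueError("nsites must be >= 1")
    if tree.n_leaves < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eig = decompose_model(model.exchangeabilities, model.composition)
    rates = model.gamma.rates
    cats = rng.integers(0, model.ncat, size=nsites)
    site_rates = rates[cats]
    root_states = rng.choice(N_STATES, size=nsites, p=model.composition)

    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    leaf_seqs: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            seq = states[id(node)]
        else:
            parent_states = states[id(node.parent)]
            seq = parent_states.copy()
            b = max(node.length, 0.0)
            if b > 0:
                # one transition matrix per gamma category for this branch
                pms = eig.transition_matrices(rates * b)
                u = rng.random(nsites)
                for c in range(model.ncat):
                    mask = cats == c
                    if not mask.any():
                        continue
                    cum = np.cumsum(pms[c], axis=1)
                    rows = cum[parent_states[mask]]
                    seq[mask] = (u[mask, None] > rows).sum(axis=1)
            states[id(node)] = seq
        if node.is_leaf:
            leaf_seqs[node.label] = "".join(AMINO_ACIDS[s] for s in seq)
        elif node.parent is not None:
            pass
    labels = tree.leaf_labels()
    return Alignment(labels, [leaf_seqs[lbl] for lbl in labels])


def random_tree(ntaxa: int, total_length: float, seed: int | np.random.Generator) -> PhyloTree:
    """Random unrooted binary topology by sequential random edge addition;
    exponential branch lengths rescaled so they sum to ``total_length``."""
    if ntaxa < 3:
        raise ValueError("ntaxa must be >= 3")
    if total_length <= 0:
        raise ValueError("total_length must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node()
    edges: list[Node] = []
    for k in range(3):
        edges.append(root.add(Node(label=f"t{k + 1}")))
    for k in range(3, ntaxa):
        target = edges[rng.integers(0, len(edges))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        leaf = mid.add(Node(label=f"t{k + 1}"))
        edges.extend([mid, leaf])
    lengths = rng.exponential(1.0, size=len(edges))
    lengths *= total_length / lengths.sum()
    for e, b in zip(edges, lengths):
        e.length = float(b)
    return PhyloTree(root)


def random_model(
    seed: int | np.random.Generator,
    concentration: float = 1.0,
    alpha: float | None = None,
    ncat: int = 4,
    name: str = "random",
) -> SubstitutionModel:
    """Random GTR20 model: Dirichlet exchangeabilities and composition,
    log-uniform gamma shape in [0.2, 5] unless given."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ex = rng.dirichlet(np.full(N_PAIRS, concentration))
    comp = rng.dirichlet(np.full(N_STATES, concentration))
    comp = np.maximum(comp, 1e-6)
    comp /= comp.sum()
    if alpha is None:
        alpha = float(np.exp(rng.uniform(np.log(0.2), np.log(5.0))))
    return SubstitutionModel(
        exchangeabilities=normalize_exchangeabilities(np.maximum(ex, 1e-12)),
        composition=comp,
        alpha=alpha,
        ncat=ncat,
        name=name,
    )


def branch_substitution_summary(tree: PhyloTree, nsites: int) -> dict:
    """Expected substitutions per branch at a given alignment length."""
    if nsites < 1:
        raise ValueError("nsites must be >= 1")
    per_branch = {  # keyed by child label where available
        i: n.length * nsites for i, n in enumerate(tree.edges())
    }
    values = np.array(list(per_branch.values()))
    return {
        "per_branch": values,
        "mean": float(values.mean()),
        "total": float(values.sum()),
        "n_branches": len(values),
    }
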