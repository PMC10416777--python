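"""Unconstrained ML tree search under a fixed substitution model.

Pipeline: neighbor-joining starting tree on pairwise ML distances, then
coordinate-wise branch-length optimisation (Brent per edge, exact partials
refreshed along a depth-first sweep so every 1-D problem sees current
values), then NNI hill-climbing with best-improvement acceptance and local
branch-length re-optimisation around each candidate swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .alphabet import N_STATES
from .likelihood import Alignment, SitePatterns, compress_patterns, _check_labels
from .model import SubstitutionModel, decompose_model
from .trees import Node, PhyloTree

_BL_MIN, _BL_MAX = 1e-8, 20.0
_TINY = 1e-300


@dataclass
class TreeSearchResult:
    tree: PhyloTree
    log_likelihood: float
    nni_rounds: int
    improvements_accepted: int
    move_log: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# engine: likelihood + branch-length machinery on a mutable tree
# ---------------------------------------------------------------------------

class TreeEngine:
    """Likelihood engine bound to a (mutable) tree and fixed site patterns."""

    def __init__(self, tree: PhyloTree, pats: SitePatterns, model: SubstitutionModel):
        _check_labels(tree, pats.labels)
        self.tree = tree
        self.pats = pats
        self.model = model
        self.eigen = decompose_model(model.exchangeabilities, model.composition)
        self.rates = model.gamma.rates
        self.ncat = model.ncat
        self.pi = model.composition
        self.weights = pats.weights
        row_of = {lbl: i for i, lbl in enumerate(pats.labels)}
        eye = np.vstack([np.eye(N_STATES), np.ones(N_STATES)])
        self._leaf_partial = {}
        for leaf in tree.leaves():
            codes = pats.patterns[row_of[leaf.label]]
            self._leaf_partial[id(leaf)] = np.ascontiguousarray(eye[codes].T)
        self._down: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- messages ------------------------------------------------------------
    def _pmats(self, t: float) -> np.ndarray:
        return self.eigen.transition_matrices(self.rates * max(t, 0.0))

    def _compute_down(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """Partial likelihood of the subtree below ``node`` (scaled)."""
        if node.is_leaf:
            lp = self._leaf_partial[id(node)]
            part = np.broadcast_to(lp, (self.ncat, N_STATES, lp.shape[1]))
            return part, None
        part, scale = None, None
        for child in node.children:
            msg, s = self._message(child)
            part = msg if part is None else part * msg
            if s is not None:
                scale = s if scale is None else scale + s
        m = part.max(axis=1)
        np.clip(m, _TINY, None, out=m)
        part = part / m[:, None, :]
        lm = np.log(m)
        scale = lm if scale is None else scale + lm
        return part, scale

    def _message(self, child: Node) -> tuple[np.ndarray, np.ndarray]:
        down, scale = self._down_cached(child)
        pm = self._pmats(child.length)
        return np.matmul(pm, down), scale

    def _down_cached(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        hit = self._down.get(id(node))
        if hit is None:
            hit = self._compute_down(node)
            self._down[id(node)] = hit
        return hit

    def _refresh_down(self, node: Node) -> None:
        self._down[id(node)] = self._compute_down(node)

    def fill_down(self) -> None:
        self._down.clear()
        for node in self.tree.postorder():
            if not node.is_leaf:
                self._down[id(node)] = self._compute_down(node)
            else:
                self._down[id(node)] = self._compute_down(node)

    # -- likelihood ------------------------------------------------------------
    def log_likelihood(self) -> float:
        self.fill_down()
        part, scale = self._down[id(self.tree.root)]
        percat = np.einsum("j,cjs->cs", self.pi, part)
        logcat = np.log(np.clip(percat, _TINY, None))
        if scale is not None:
            logcat = logcat + scale
        mx = logcat.max(axis=0)
        site = mx + np.log(np.exp(logcat - mx).sum(axis=0)) - np.log(self.ncat)
        return float(np.dot(self.weights, site))

    def _edge_logl(self, outer: np.ndarray, oscale, down: np.ndarray, dscale, t: float) -> float:
        """logL as a function of one branch length, everything else fixed."""
        pm = self._pmats(t)
        md = np.matmul(pm, down)
        percat = np.einsum("j,cjs,cjs->cs", self.pi, outer, md)
        logcat = np.log(np.clip(percat, _TINY, None))
        if oscale is not None:
            logcat = logcat + oscale
        if dscale is not None:
            logcat = logcat + dscale
        mx = logcat.max(axis=0)
        site = mx + np.log(np.exp(logcat - mx).sum(axis=0)) - np.log(self.ncat)
        return float(np.dot(self.weights, site))

    def _optimize_edge(self, outer, oscale, node: Node) -> float:
        down, dscale = self._down_cached(node)
        res = minimize_scalar(
            lambda t: -self._edge_logl(outer, oscale, down, dscale, t),
            bounds=(_BL_MIN, _BL_MAX),
            method="bounded",
            options={"xatol": 1e-8},
        )
        cur = -self._edge_logl(outer, oscale, down, dscale, node.length)
        if res.fun < cur:
            node.length = float(res.x)
        return float(-min(res.fun, cur))

    def _outer_for_child(self, node: Node, child: Node, inner, iscale):
        """Outer partial at ``node`` excluding ``child``'s subtree; ``inner``
        is the message arriving at ``node`` from above (None at the root)."""
        part, scale = inner, iscale
        for sib in node.children:
            if sib is child:
                continue
            msg, s = self._message(sib)
            part = msg if part is None else part * msg
            if s is not None:
                scale = s if scale is None else scale + s
        if part is None:  # root with a single child
            npat = self.pats.patterns.shape[1]
            part = np.ones((self.ncat, N_STATES, npat))
        return part, scale

    # -- sweeps ------------------------------------------------------------
    def optimize_all_lengths(self, tol: float = 1e-6, max_sweeps: int = 20) -> float:
        """Sweep every edge with fresh partials until the per-sweep logL gain
        drops below ``tol``.  The gain is nonnegative by construction: each
        1-D move is accepted only if it improves its exact local objective."""
        prev = self.log_likelihood()
        for _ in range(max_sweeps):
            self.fill_down()
            self._sweep(self.tree.root, None, None)
            cur = self.log_likelihood()
            if cur - prev < tol:
                return cur
            prev = cur
        return prev

    def _sweep(self, node: Node, inner, iscale) -> None:
        for child in node.children:
            outer, oscale = self._outer_for_child(node, child, inner, iscale)
            self._optimize_edge(outer, oscale, child)
            if not child.is_leaf:
                pm = self._pmats(child.length)
                nxt = np.matmul(pm.transpose(0, 2, 1), outer)
                m = nxt.max(axis=1)
                np.clip(m, _TINY, None, out=m)
                nxt /= m[:, None, :]
                nscale = np.log(m) if oscale is None else oscale + np.log(m)
                self._sweep(child, nxt, nscale)
            # child's subtree lengths are final for this sweep: refresh its
            # cached down partial so later siblings see current values
            self._refresh_down(child)

    def optimize_edges(self, targets: list[Node], passes: int = 1) -> float:
        """Optimise only the listed edges (each identified by its child node),
        refreshing partials exactly; used for local NNI re-optimisation."""
        best = -np.inf
        for _ in range(passes):
            for child in targets:
                self.fill_down()
                node = child.parent
                inner, iscale = self._inner_at(node)
                outer, oscale = self._outer_for_child(node, child, inner, iscale)
                best = self._optimize_edge(outer, oscale, child)
        return best

    def _inner_at(self, node: Node):
        """Message arriving at ``node`` from above (None at the root)."""
        if node.parent is None:
            return None, None
        inner, iscale = self._inner_at(node.parent)
        outer, oscale = self._outer_for_child(node.parent, node, inner, iscale)
        pm = self._pmats(node.length)
        nxt = np.matmul(pm.transpose(0, 2, 1), outer)
        m = nxt.max(axis=1)
        np.clip(m, _TINY, None, out=m)
        nxt /= m[:, None, :]
        nscale = np.log(m) if oscale is None else oscale + np.log(m)
        return nxt, nscale


# ---------------------------------------------------------------------------
# pairwise ML distances and the NJ starting tree
# ---------------------------------------------------------------------------

def pairwise_ml_distance(
    codes_a: np.ndarray, codes_b: np.ndarray, model: SubstitutionModel
) -> float:
    """Two-sequence branch length maximising the likelihood under the model."""
    mask = (codes_a < N_STATES) & (codes_b < N_STATES)
    a, b = codes_a[mask], codes_b[mask]
    if a.size == 0:
        return _BL_MIN
    pair = a.astype(int) * N_STATES + b.astype(int)
    counts = np.bincount(pair, minlength=N_STATES * N_STATES).reshape(N_STATES, N_STATES)
    eigen = decompose_model(model.exchangeabilities, model.composition)
    rates = model.gamma.rates
    pi = model.composition

    def neg_logl(t):
        pms = eigen.transition_matrices(rates * t)
        lik = (pi[None, :, None] * pms).mean(axis=0)
        return -float((counts * np.log(np.clip(lik, _TINY, None))).sum())

    res = minimize_scalar(neg_logl, bounds=(_BL_MIN, _BL_MAX), method="bounded", options={"xatol": 1e-8})
    return float(res.x)


def starting_tree(aln: Alignment, model: SubstitutionModel) -> PhyloTree:
    """Neighbor joining on pairwise ML distances (negative NJ lengths clamped)."""
    if aln.n_sequences < 3:
        raise ValueError("need at least 3 sequences for a starting tree")
    import skbio

    codes = aln.codes()
    n = aln.n_sequences
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = pairwise_ml_distance(codes[i], codes[j], model)
    sk = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=aln.labels))
    import io as _io

    buf = _io.StringIO()
    sk.write(buf, format="newick")
    tree = PhyloTree.from_newick(buf.getvalue())
    for e in tree.edges():
        if e.length < _BL_MIN:
            e.length = _BL_MIN
    tree.unroot()
    return tree


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def _internal_edges(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None and not n.is_leaf and not n.parent.is_leaf]


def _nni_swaps(tree: PhyloTree) -> list[tuple[int, int, int]]:
    """Enumerate NNI moves as (edge_child_idx, v_child_pos, u_child_pos) over
    a stable postorder indexing.  For edge (u=parent, v=child), each move
    exchanges one child of v with one non-v child of u (two distinct
    topologies per edge)."""
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    moves = []
    for v in _internal_edges(tree):
        u = v.parent
        u_children = [c for c in u.children if c is not v]
        if not u_children or len(v.children) < 2:
            continue
        w = u_children[0]  # one partner suffices: both swaps with it cover
        for c in v.children[:2]:  # the two alternative topologies
            moves.append((index[id(v)], index[id(c)], index[id(w)]))
    return moves


def _apply_nni(tree: PhyloTree, move: tuple[int, int, int]) -> None:
    nodes = list(tree.postorder())
    v, c, w = nodes[move[0]], nodes[move[1]], nodes[move[2]]
    u = v.parent
    v.children[v.children.index(c)] = w
    u.children[u.children.index(w)] = c
    c.parent, w.parent = u, v


def search_ml_tree(
    aln: Alignment,
    model: SubstitutionModel,
    seed: int = 0,
    start: PhyloTree | None = None,
    nni_tol: float = 1e-4,
    bl_tol: float = 1e-6,
    max_rounds: int = 50,
) -> TreeSearchResult:
    """NNI hill-climbing ML tree search (deterministic given inputs).

    Every NNI neighbor of every internal edge is scored with local
    branch-length re-optimisation (the swapped edge and its four adjacent
    edges); the single best improving move is accepted, followed by full
    branch-length optimisation; the search stops when no move improves the
    log-likelihood by more than ``nni_tol``.
    """
    if aln.n_sequences < 4:
        raise ValueError("tree search needs at least 4 sequences")
    pats = compress_patterns(aln)
    tree = (start.copy() if start is not None else starting_tree(aln, model))
    tree.unroot()
    engine = TreeEngine(tree, pats, model)
    cur = engine.optimize_all_lengths(tol=bl_tol)

    move_log = []
    rounds = 0
    accepted = 0
    for rounds in range(1, max_rounds + 1):
        best_logl, best_state, best_key = cur, None, None
        for move in _nni_swaps(tree):
            cand = tree.copy()
            _apply_nni(cand, move)
            cand_nodes = list(cand.postorder())
            v = cand_nodes[move[0]]
            seen: dict[int, Node] = {}
            for x in [v, *v.children, v.parent, *v.parent.children]:
                if x.parent is not None:
                    seen.setdefault(id(x), x)
            local = list(seen.values())
            ce = TreeEngine(cand, pats, model)
            ce.optimize_edges(local, passes=1)
            logl = ce.log_likelihood()
            if logl > best_logl + 1e-12:
                key = _canonical_key(cand)
                if logl > best_logl + 1e-9 or best_key is None or key < best_key:
                    best_logl, best_state, best_key = logl, cand, key
        if best_state is None or best_logl - cur < nni_tol:
            break
        tree = best_state
        engine = TreeEngine(tree, pats, model)
        cur = engine.optimize_all_lengths(tol=bl_tol)
        accepted += 1
        move_log.append({"round": rounds, "log_likelihood": cur})
    final_logl = TreeEngine(tree, pats, model).log_likelihood()
    return TreeSearchResult(tree, final_logl, rounds, accepted, move_log)


def _canonical_key(tree: PhyloTree) -> str:
    return ";".join(sorted(",".join(sorted(bp)) for bp in tree.bipartitions()))


def optimize_branch_lengths(
    tree: PhyloTree, model: SubstitutionModel, aln: Alignment, tol: float = 1e-6
) -> PhyloTree:
    """Brent per-edge branch-length optimisation on a fixed topology."""
    pats = compress_patterns(aln)
    out = tree.copy()
    engine = TreeEngine(out, pats, model)
    engine.optimize_all_lengths(tol=tol)
    return out
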