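"""Tree likelihood under GTR20+Gamma via Felsenstein pruning.

The engine compresses alignment columns into unique site patterns, runs a
post-order pass with per-node scaling vectors (log-scale accumulators) to
guard against underflow, and mixes over discrete-gamma categories by scaling
branch lengths with each category rate.  A backward (pre-order) pass yields
analytic gradients of the log-likelihood with respect to the exchangeability
and composition parameters through the spectral decomposition of the
symmetrised rate matrix; these drive the maximum-likelihood estimator.

``brute_force_log_likelihood`` marginalises explicitly over all internal
node states and serves as the exact reference on tiny trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alphabet import N_PAIRS, N_STATES, PAIR_INDICES, encode_sequence
from .model import ModelEigensystem, SubstitutionModel, decompose_model, pairs_to_matrix
from .trees import Node, PhyloTree

_TINY = 1e-300


@dataclass
class Alignment:
    """Equal-length residue sequences with unique labels."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def codes(self) -> np.ndarray:
        """Integer-coded matrix, shape (n_sequences, n_sites); missing = 20."""
        return np.vstack([encode_sequence(s) for s in self.sequences])


@dataclass
class SitePatterns:
    """Unique alignment columns with multiplicities, in first-occurrence order."""

    labels: list[str]
    patterns: np.ndarray  # (n_sequences, n_patterns) int codes
    weights: np.ndarray  # (n_patterns,) multiplicities

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())


def compress_patterns(aln: Alignment) -> SitePatterns:
    codes = aln.codes()
    if codes.shape[1] == 0:
        return SitePatterns(list(aln.labels), codes, np.zeros(0))
    cols, first, counts = np.unique(codes, axis=1, return_index=True, return_counts=True)
    order = np.argsort(first)
    return SitePatterns(list(aln.labels), cols[:, order], counts[order].astype(float))


def _check_labels(tree: PhyloTree, labels: list[str]) -> None:
    tl, al = set(tree.leaf_labels()), set(labels)
    if tl != al:
        only_tree = sorted(tl - al)
        only_aln = sorted(al - tl)
        raise ValueError(
            f"tree/alignment label mismatch: only in tree {only_tree}, only in alignment {only_aln}"
        )


class PruningEngine:
    """Reusable likelihood/gradient evaluator for a fixed tree and alignment.

    The tree's topology and branch lengths are frozen at construction; the
    model (exchangeabilities, composition, alpha) can be swapped cheaply,
    which is what the ML optimiser and the MCMC sampler iterate over.
    """

    def __init__(self, tree: PhyloTree, aln: Alignment | SitePatterns):
        if isinstance(aln, Alignment):
            pats = compress_patterns(aln)
        else:
            pats = aln
        _check_labels(tree, pats.labels)
        row_of = {lbl: i for i, lbl in enumerate(pats.labels)}
        self.patterns = pats.patterns
        self.weights = pats.weights
        self.n_patterns = pats.patterns.shape[1]

        self.nodes: list[Node] = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[index[id(c)] for c in n.children] for n in self.nodes]
        self.parent = [index[id(n.parent)] if n.parent is not None else -1 for n in self.nodes]
        self.lengths = np.array([max(n.length, 0.0) for n in self.nodes])
        self.leaf_row = [row_of[n.label] if n.is_leaf else -1 for n in self.nodes]
        self.root_index = index[id(tree.root)]

        eye = np.vstack([np.eye(N_STATES), np.ones(N_STATES)])  # row 20 = missing
        self.leaf_partials = {
            i: np.ascontiguousarray(eye[self.patterns[self.leaf_row[i]]].T)
            for i, ch in enumerate(self.children)
            if not ch
        }
        self.leaf_partials_t = {i: np.ascontiguousarray(p.T) for i, p in self.leaf_partials.items()}
        # filled by _forward
        self._partials: dict[int, np.ndarray] = {}
        self._scales: dict[int, np.ndarray] = {}
        self._messages: dict[int, np.ndarray] = {}
        self._msg_scales: dict[int, np.ndarray] = {}
        self._pmats: dict[int, np.ndarray] = {}

    # -- model binding ------------------------------------------------------
    def set_model(self, model: SubstitutionModel) -> None:
        self.set_parameters(model.exchangeabilities, model.composition, model.alpha, model.ncat)

    def set_parameters(self, ex: np.ndarray, comp: np.ndarray, alpha: float, ncat: int = 4) -> None:
        from .model import discretize_gamma

        self.ex = np.asarray(ex, dtype=float)
        comp = np.asarray(comp, dtype=float)
        self.comp = comp / comp.sum()
        self.alpha = float(alpha)
        self.ncat = int(ncat)
        self.eigen: ModelEigensystem = decompose_model(self.ex, self.comp)
        self.rates = discretize_gamma(alpha, ncat).rates

    # -- forward pass -------------------------------------------------------
    def _edge_pmats(self, i: int) -> np.ndarray:
        return self.eigen.transition_matrices(self.rates * self.lengths[i])

    def _forward(self, keep_messages: bool = False) -> None:
        self._partials.clear()
        self._scales.clear()
        if keep_messages:
            self._messages.clear()
            self._msg_scales.clear()
            self._pmats.clear()
        npat, ncat = self.n_patterns, self.ncat
        for i, ch in enumerate(self.children):
            if not ch:
                continue
            scale = np.zeros((ncat, npat))
            msgs = []
            for c in ch:
                pm = self._edge_pmats(c)
                sub = self.leaf_partials.get(c)
                if sub is not None:
                    msg = np.matmul(pm, sub[None, :, :])
                else:
                    msg = np.matmul(pm, self._partials[c])
                    scale += self._scales[c]
                msgs.append(msg)
                if keep_messages:
                    self._messages[c] = msg
                    self._msg_scales[c] = self._scales.get(c)  # None for leaves
                    self._pmats[c] = pm
            if len(msgs) == 1:
                part = msgs[0] if not keep_messages else msgs[0].copy()
            else:
                part = msgs[0] * msgs[1]  # fresh buffer: stored messages stay intact
                for msg in msgs[2:]:
                    part *= msg
            m = part.max(axis=1)
            np.clip(m, _TINY, None, out=m)
            part /= m[:, None, :]
            scale += np.log(m)
            self._partials[i] = part
            self._scales[i] = scale

    def _site_logls(self) -> np.ndarray:
        """Per-pattern log-likelihoods (natural log), after a forward pass."""
        r = self.root_index
        if self.children[r]:
            root_part, root_scale = self._partials[r], self._scales[r]
        else:  # degenerate single-leaf tree
            root_part = self.leaf_partials[r][None].repeat(self.ncat, axis=0)
            root_scale = np.zeros((self.ncat, self.n_patterns))
        percat = np.einsum("j,cjs->cs", self.comp, root_part)
        logcat = np.log(np.clip(percat, _TINY, None)) + root_scale
        mx = logcat.max(axis=0)
        site = mx + np.log(np.exp(logcat - mx).sum(axis=0)) - np.log(self.ncat)
        return site

    def log_likelihood(self) -> float:
        self._forward()
        return float(np.dot(self.weights, self._site_logls()))

    # -- backward pass: analytic gradient ------------------------------------
    def log_likelihood_and_gradient(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Returns (logL, d logL/d exchangeabilities (190), d logL/d composition (20)).

        Derivatives are with respect to the raw (unnormalised) parameters;
        the rate-matrix normalisations are differentiated through.
        """
        self._forward(keep_messages=True)
        site = self._site_logls()
        logl = float(np.dot(self.weights, site))

        ncat, npat = self.ncat, self.n_patterns
        eig = self.eigen
        v, lam = eig.eigenvectors, eig.eigenvalues
        sqrt_pi, inv_sqrt_pi = eig.sqrt_pi, eig.inv_sqrt_pi
        pi = self.comp / self.comp.sum()

        r = self.root_index
        root_part, root_scale = self._partials[r], self._scales[r]
        # root prior term of the composition gradient
        root_w = np.exp(root_scale - site[None, :]) * self.weights[None, :] / ncat
        g_comp_root = np.einsum("cs,cjs->j", root_w, root_part)

        ksum = np.zeros((N_STATES, N_STATES))
        sp_row = np.zeros(N_STATES)  # accumulated row sums of S.P over edges
        sp_col = np.zeros(N_STATES)

        # X[i]: outer partial at parent(i) excluding subtree i, with pi folded
        # in at the root; sx[i]: its log-scale (per category and pattern).
        stack: list[tuple[int, np.ndarray, np.ndarray]] = []
        x_root = np.broadcast_to(pi[None, :, None], (ncat, N_STATES, npat))
        stack.append((r, x_root, np.zeros((ncat, npat))))
        while stack:
            u, d_u, sd_u = stack.pop()
            ch = self.children[u]
            for c in ch:
                x, sx = d_u, sd_u
                for w in ch:
                    if w != c:
                        x = x * self._messages[w]
                        ws = self._msg_scales[w]
                        if ws is not None:
                            sx = sx + ws

                down = self.leaf_partials.get(c)
                if down is not None:
                    down_t = self.leaf_partials_t[c][None]
                    sdown = None
                else:
                    down_t = np.ascontiguousarray(self._partials[c].transpose(0, 2, 1))
                    sdown = self._scales[c]
                arg = sx + sdown - site[None, :] if sdown is not None else sx - site[None, :]
                omega = np.exp(arg)
                omega *= self.weights[None, :] / ncat
                xw = x * omega[:, None, :]
                s_ec = np.matmul(xw, down_t)  # (ncat, 20, 20)

                pm = self._pmats[c]
                sp = s_ec * pm
                sp_row += sp.sum(axis=(0, 2))
                sp_col += sp.sum(axis=(0, 1))

                # K_ec = (V^T D1 S D2 V) o G_ec, accumulated over categories
                taus = self.rates * self.lengths[c]
                a_mid = np.matmul(
                    np.matmul(v.T[None], inv_sqrt_pi[None, :, None] * s_ec * sqrt_pi[None, None, :]),
                    v[None],
                )
                for k in range(ncat):
                    g = _divided_differences(lam, taus[k])
                    ksum += a_mid[k] * g

                if self.children[c]:
                    d_c = np.matmul(pm.transpose(0, 2, 1), x)
                    mc = d_c.max(axis=1)  # per (cat, pattern) rescale
                    np.clip(mc, _TINY, None, out=mc)
                    d_c /= mc[:, None, :]
                    stack.append((c, d_c, sx + np.log(mc)))

        w_mat = v @ ksum @ v.T
        w_mat = 0.5 * (w_mat + w_mat.T)

        # chain through B = D2 (Qtilde / c) D1
        rmat = pairs_to_matrix(self.ex / self.ex.sum())
        u_vec = rmat @ pi
        c_norm = float(pi @ u_vec)
        b_mat = sqrt_pi[:, None] * (rmat * pi[None, :]) * inv_sqrt_pi[None, :]
        np.fill_diagonal(b_mat, -u_vec)
        b_mat /= c_norm
        wb = float((w_mat * b_mat).sum())

        # exchangeability gradient (w.r.t. the normalised 190-vector)
        pair_i = np.array([p[0] for p in PAIR_INDICES])
        pair_j = np.array([p[1] for p in PAIR_INDICES])
        s_ij = sqrt_pi[pair_i] * sqrt_pi[pair_j]
        g_ex_norm = (
            2.0 * w_mat[pair_i, pair_j] * s_ij
            - np.diag(w_mat)[pair_i] * pi[pair_j]
            - np.diag(w_mat)[pair_j] * pi[pair_i]
        ) / c_norm - wb * 2.0 * pi[pair_i] * pi[pair_j] / c_norm
        # chain through the simplex normalisation ex -> ex/sum(ex)
        ex = self.ex
        tot = ex.sum()
        exn = ex / tot
        g_ex = (g_ex_norm - float(g_ex_norm @ exn)) / tot

        # composition gradient: dB/dpi_m terms + D1/D2 terms + root prior,
        # then chain through pi -> pi/sum(pi)
        g_pi_norm = np.empty(N_STATES)
        diag_w = np.diag(w_mat)
        dc_dpi = 2.0 * u_vec
        for m in range(N_STATES):
            db = np.zeros((N_STATES, N_STATES))
            # off-diagonal: d(r_ij sqrt(pi_i pi_j)/c)/dpi_m
            db[m, :] = rmat[m, :] * sqrt_pi / (2.0 * sqrt_pi[m])
            db[:, m] += rmat[:, m] * sqrt_pi / (2.0 * sqrt_pi[m])
            db /= c_norm
            db -= b_mat * (dc_dpi[m] / c_norm)
            # diagonal: d(-u_i/c)/dpi_m  (overwrite, the line above already
            # subtracted the c-derivative part of the old diagonal)
            np.fill_diagonal(db, 0.0)
            dd = -rmat[:, m] / c_norm + u_vec * dc_dpi[m] / (c_norm**2)
            db[np.diag_indices(N_STATES)] = dd
            g_pi_norm[m] = float((w_mat * db).sum())
        g_pi_norm += (sp_col - sp_row) / (2.0 * pi)
        g_pi_norm += g_comp_root
        comp = self.comp
        ctot = comp.sum()
        compn = comp / ctot
        g_comp = (g_pi_norm - float(g_pi_norm @ compn)) / ctot

        return logl, g_ex, g_comp


def _divided_differences(lam: np.ndarray, tau: float) -> np.ndarray:
    """G[x,y] = (e^{lam_x tau} - e^{lam_y tau}) / (lam_x - lam_y), with the
    confluent limit tau * e^{lam tau} on (numerically) equal eigenvalues."""
    e = np.exp(lam * tau)
    diff_l = lam[:, None] - lam[None, :]
    diff_e = e[:, None] - e[None, :]
    near = np.abs(diff_l) < 1e-12
    g = np.where(near, tau * np.exp(0.5 * (lam[:, None] + lam[None, :]) * tau), diff_e / np.where(near, 1.0, diff_l))
    return g


def log_likelihood(tree: PhyloTree, model: SubstitutionModel, aln: Alignment | SitePatterns) -> float:
    """Log-likelihood (natural-log units) of the alignment on the tree."""
    engine = PruningEngine(tree, aln)
    engine.set_model(model)
    return engine.log_likelihood()


def brute_force_log_likelihood(tree: PhyloTree, model: SubstitutionModel, aln: Alignment) -> float:
    """Exact likelihood by explicit marginalisation over internal states.

    Refuses trees with more than 4 internal nodes (20^5 state assignments
    would be pointless as an oracle).
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    if len(internal) > 4:
        raise ValueError(f"brute force limited to 4 internal nodes, tree has {len(internal)}")
    _check_labels(tree, aln.labels)
    codes = aln.codes()
    row_of = {lbl: i for i, lbl in enumerate(aln.labels)}
    eig = decompose_model(model.exchangeabilities, model.composition)
    rates = model.gamma.rates
    ncat = model.ncat
    int_index = {id(n): k for k, n in enumerate(internal)}
    pmats = {id(n): eig.transition_matrices(rates * max(n.length, 0.0)) for n in nodes if n.parent is not None}

    nsites = aln.n_sites
    total = 0.0
    for s in range(nsites):
        site_l = 0.0
        for c in range(ncat):
            acc = 0.0
            for assign in itertools.product(range(N_STATES), repeat=len(internal)):
                p = model.composition[assign[int_index[id(tree.root)]]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    ps = assign[int_index[id(n.parent)]]
                    pm = pmats[id(n)][c]
                    if n.is_leaf:
                        obs = codes[row_of[n.label], s]
                        p *= 1.0 if obs == N_STATES else pm[ps, obs]
                    else:
                        p *= pm[ps, assign[int_index[id(n)]]]
                acc += p
            site_l += acc / ncat
        total += np.log(site_l)
    return float(total)
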