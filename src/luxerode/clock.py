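"""Maximum-likelihood molecular-clock model fitting and rate testing.

Fits a strict global clock (null) and a one-clade local clock (alternative,
one extra rate multiplier r applied to a designated monophyletic foreground
clade including its stem branch) on a fixed rooted topology, and compares
them with a likelihood-ratio test: LR = 2(lnLA - lnL0) against chi-square
with df = 1.

Node heights are measured in expected substitutions per site (the background
rate is absorbed into the heights: without calibrations only their product is
identifiable), so the background rate is reported as 1. Likelihoods are
computed by Felsenstein pruning with per-pattern log scaling and site-pattern
compression; transition probabilities come from the symmetric eigendecomposition
diag(pi)^{1/2} Q diag(pi)^{-1/2} of the reversible rate matrix.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .io import MultipleAlignment, read_tree

log = logging.getLogger(__name__)

NT_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

_MIN_HEIGHT = 1e-9  # keeps matrix exponentials well-conditioned
_R_MIN, _R_MAX = 1e-3, 1e3


# ---------------------------------------------------------------------------
# substitution models


def _discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete-gamma categories (mean 1)."""
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
    # mean within [a,b] of Gamma(alpha, 1/alpha): uses the shape+1 identity
    upper = special.gammainc(alpha + 1, edges[1:] * alpha)
    lower = special.gammainc(alpha + 1, edges[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible substitution model Q = S diag(pi), rescaled to 1 sub/site.

    ``exchangeabilities`` must be symmetric with non-negative off-diagonals
    (non-reversible inputs are rejected); ``freqs`` are normalized to sum 1.
    Optional discrete-gamma rate heterogeneity with ``gamma_ncat`` categories
    averaged with equal weights.
    """

    alphabet: str  # "nt" or "aa"
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    gamma_shape: float | None = None
    gamma_ncat: int = 4
    states: str = field(init=False)

    def __post_init__(self):
        self.states = NT_STATES if self.alphabet == "nt" else AA_STATES
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        n = len(self.states)
        if S.shape != (n, n):
            raise ValueError(f"exchangeability matrix must be {n}x{n}")
        if not np.allclose(S, S.T):
            raise ValueError("non-reversible model: exchangeabilities not symmetric")
        off = S[~np.eye(n, dtype=bool)]
        if (off < 0).any():
            raise ValueError("negative exchangeability")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q = Q / scale
        self.Q = Q
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2)
        self._eval = w
        self._left = U / sqrt_pi[:, None]
        self._right = U.T * sqrt_pi[None, :]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def gamma_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        return _discrete_gamma_rates(self.gamma_shape, self.gamma_ncat)

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; shape (len(t), n, n)."""
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        expwt = np.exp(self._eval[None, :] * t[:, None])
        P = np.einsum("ik,ek,kj->eij", self._left, expwt, self._right)
        np.clip(P, 0.0, 1.0, out=P)
        return P / P.sum(axis=2, keepdims=True)


def jc() -> SubstitutionModel:
    S = np.ones((4, 4)) - np.eye(4)
    return SubstitutionModel("nt", S, np.full(4, 0.25))


def hky(kappa: float = 2.0, freqs=None) -> SubstitutionModel:
    S = np.ones((4, 4)) - np.eye(4)
    # transitions: A<->G (0,2) and C<->T (1,3)
    S[0, 2] = S[2, 0] = S[1, 3] = S[3, 1] = kappa
    return SubstitutionModel("nt", S, np.full(4, 0.25) if freqs is None else freqs)


def gtr(rates, freqs, gamma_shape=None, gamma_ncat=4) -> SubstitutionModel:
    """GTR from 6 upper-triangle exchangeabilities (AC, AG, AT, CG, CT, GT)."""
    S = np.zeros((4, 4))
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for (i, j), r in zip(idx, rates):
        S[i, j] = S[j, i] = r
    return SubstitutionModel("nt", S, freqs, gamma_shape, gamma_ncat)


def empirical_frequencies(alignment: MultipleAlignment,
                          states: str = NT_STATES) -> np.ndarray:
    """Observed state frequencies across an alignment (gaps ignored).

    Substitution parameters are estimated once from the data and held fixed
    across the null and alternative clock fits, so the two models differ by
    the rate multiplier alone (df = 1).
    """
    counts = np.zeros(len(states))
    idx = {c: i for i, c in enumerate(states)}
    for seq in alignment.sequences:
        for ch in seq:
            i = idx.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise ValueError("no countable states in alignment")
    return counts / counts.sum()


def poisson_aa() -> SubstitutionModel:
    S = np.ones((20, 20)) - np.eye(20)
    return SubstitutionModel("aa", S, np.full(20, 0.05))


def read_paml_rate_matrix(path) -> SubstitutionModel:
    """Empirical amino-acid model from a PAML-dialect rate-matrix file.

    Format: 19 lines of lower-triangle exchangeabilities followed by a line
    (or lines) of 20 equilibrium frequencies; blank lines and '#' comments
    are ignored.
    """
    numbers = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            numbers.extend(float(x) for x in line.split())
    need = 190 + 20
    if len(numbers) < need:
        raise ValueError(f"PAML matrix file: expected >= {need} numbers, "
                         f"got {len(numbers)}")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = numbers[k]
            k += 1
    freqs = np.array(numbers[190:210])
    return SubstitutionModel("aa", S, freqs)


# ---------------------------------------------------------------------------
# rooted-topology arrays


class _Topology:
    """Array view of a rooted binary topology for fast pruning."""

    def __init__(self, tree: dendropy.Tree):
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValueError("topology must be rooted (bifurcating root)")
        # postorder indexing guarantees children precede parents
        post = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(post)}
        self.n_nodes = len(post)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children = [[] for _ in range(self.n_nodes)]
        self.labels = [None] * self.n_nodes
        for n in post:
            i = self.index[id(n)]
            if n.parent_node is not None:
                p = self.index[id(n.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            if n.is_leaf():
                self.labels[i] = n.taxon.label if n.taxon else str(n)
        self.postorder = list(range(self.n_nodes))  # postorder_node_iter order
        self.root = self.index[id(root)]
        self.leaves = [i for i in range(self.n_nodes) if not self.children[i]]
        self.internal = [i for i in range(self.n_nodes) if self.children[i]]
        self.leaf_labels = [self.labels[i] for i in self.leaves]

    def clade_nodes(self, labels: set) -> list:
        """Node ids of the MRCA subtree of ``labels``; errors unless monophyletic."""
        want = set(labels)
        missing = want - set(self.leaf_labels)
        if missing:
            raise ValueError(f"foreground taxa not in tree: {sorted(missing)}")
        below = [set() for _ in range(self.n_nodes)]
        for i in self.postorder:
            if not self.children[i]:
                below[i] = {self.labels[i]}
            else:
                for c in self.children[i]:
                    below[i] |= below[c]
        mrca = min((i for i in range(self.n_nodes) if want <= below[i]),
                   key=lambda i: len(below[i]))
        if below[mrca] != want:
            raise ValueError(
                f"foreground clade is not monophyletic: MRCA also contains "
                f"{sorted(below[mrca] - want)}")
        out = []
        stack = [mrca]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return read_tree(tree)


def _compress(alignment: MultipleAlignment, labels, states: str):
    """Site-pattern compression; returns (leaf_codes (ntax,npat), weights)."""
    code = {c: i for i, c in enumerate(states)}
    mat = np.array([[code.get(ch, -1) for ch in alignment[lab]]
                    for lab in labels], dtype=np.int32)
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float)


def _pattern_loglik(topo: _Topology, lengths: np.ndarray, patterns, model):
    """Per-pattern log-likelihood via pruning with log scaling."""
    n_states = model.n_states
    npat = patterns.shape[1]
    rates = model.gamma_rates()
    percat = np.empty((len(rates), npat))
    leaf_row = {node: r for r, node in enumerate(topo.leaves)}
    for ci, rate in enumerate(rates):
        P = model.transition_matrices(lengths * rate)
        partial = np.empty((topo.n_nodes, npat, n_states))
        scale = np.zeros(npat)
        for i in topo.postorder:
            if not topo.children[i]:
                codes = patterns[leaf_row[i]]
                L = np.zeros((npat, n_states))
                known = codes >= 0
                L[known, codes[known]] = 1.0
                L[~known, :] = 1.0
                partial[i] = L
            else:
                L = np.ones((npat, n_states))
                for c in topo.children[i]:
                    L *= partial[c] @ P[c].T
                mx = L.max(axis=1)
                mx[mx == 0] = 1.0
                L /= mx[:, None]
                scale += np.log(mx)
                partial[i] = L
        site = partial[topo.root] @ model.pi
        site[site <= 0] = 1e-300
        percat[ci] = np.log(site) + scale
    if len(rates) == 1:
        return percat[0]
    return special.logsumexp(percat, axis=0) - np.log(len(rates))


def prune_likelihood(tree, alignment: MultipleAlignment,
                     model: SubstitutionModel) -> float:
    """Log-likelihood of an alignment on a tree with fixed branch lengths."""
    t = _as_tree(tree)
    topo = _Topology(t)
    missing = [lab for lab in topo.leaf_labels if lab not in alignment.sequence_ids]
    if missing:
        raise ValueError(f"taxa missing from alignment: {missing}")
    lengths = np.zeros(topo.n_nodes)
    for n in t.postorder_node_iter():
        i = topo.index[id(n)]
        if n.parent_node is not None:
            lengths[i] = n.edge.length or 0.0
    patterns, weights = _compress(alignment, topo.leaf_labels, model.states)
    return float(_pattern_loglik(topo, lengths, patterns, model) @ weights)


# ---------------------------------------------------------------------------
# clock fits


@dataclass
class ClockFit:
    """A fitted clock model on a fixed rooted topology.

    Heights are in expected substitutions per site; branch length =
    (parent height - child height) * (r on foreground branches, else 1).
    """

    tree_newick: str
    node_heights: dict
    background_rate: float
    foreground: frozenset | None
    rate_multiplier: float
    log_likelihood: float
    converged: bool
    n_free_params: int


def _heights_from_params(topo: _Topology, x_heights: np.ndarray,
                         internal_order: list) -> np.ndarray:
    h = np.zeros(topo.n_nodes)
    root_h = np.exp(x_heights[0])
    h[topo.root] = root_h
    fracs = 1.0 / (1.0 + np.exp(-x_heights[1:]))
    # preorder: parents before children (reverse postorder)
    frac_of = dict(zip(internal_order, fracs))
    for i in reversed(topo.postorder):
        if topo.children[i] and i != topo.root:
            h[i] = frac_of[i] * h[topo.parent[i]]
    return np.maximum(h, 0.0)


def _branch_lengths(topo: _Topology, h: np.ndarray, r: float,
                    fg_nodes: set) -> np.ndarray:
    lengths = np.zeros(topo.n_nodes)
    for i in range(topo.n_nodes):
        p = topo.parent[i]
        if p >= 0:
            d = max(h[p] - h[i], _MIN_HEIGHT)
            lengths[i] = d * (r if i in fg_nodes else 1.0)
    return lengths


def _init_root_height(alignment, labels) -> float:
    """Half the maximal pairwise JC distance as a starting root height."""
    seqs = [alignment[lab] for lab in labels]
    n = len(seqs)
    dmax = 0.01
    for i in range(n):
        for j in range(i + 1, min(i + 4, n)):  # a few pairs suffice for an init
            a, b = seqs[i], seqs[j]
            cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not cols:
                continue
            p = sum(x != y for x, y in cols) / len(cols)
            p = min(p, 0.70)
            d = -0.75 * np.log(1 - 4 * p / 3)
            dmax = max(dmax, d)
    return max(dmax / 2, 0.005)


def _fit_clock(tree, alignment, model, foreground=None, include_stem=True,
               extra_starts=()):
    t = _as_tree(tree)
    topo = _Topology(t)
    missing = [lab for lab in topo.leaf_labels if lab not in alignment.sequence_ids]
    if missing:
        raise ValueError(f"taxa missing from alignment: {missing}")
    patterns, weights = _compress(alignment, topo.leaf_labels, model.states)
    internal_order = [i for i in topo.internal if i != topo.root]
    fg_nodes: set = set()
    free_r = foreground is not None
    if free_r:
        fg = set(foreground)
        if fg == set(topo.leaf_labels):
            log.warning("foreground covers all taxa: rate multiplier r is not "
                        "identifiable separately from the heights; only the "
                        "product r*height is meaningful")
        clade = topo.clade_nodes(fg)  # clade[0] is the MRCA
        if topo.parent[clade[0]] == topo.root and include_stem:
            log.warning(
                "foreground clade is a child of the root: no background path "
                "crosses the root, so the root height can absorb the rate "
                "multiplier (pulley principle) and r may be unidentifiable")
        fg_nodes = set(clade)
        if not include_stem:
            # the MRCA's own edge is the stem; keep it at the background rate
            fg_nodes.discard(clade[0])
    n_h = 1 + len(internal_order)

    def negll(x):
        h = _heights_from_params(topo, x[:n_h], internal_order)
        r = float(np.exp(x[n_h])) if free_r else 1.0
        lengths = _branch_lengths(topo, h, r, fg_nodes)
        return -float(_pattern_loglik(topo, lengths, patterns, model) @ weights)

    if extra_starts:
        # informed starts (e.g. the null optimum) supersede the generic one
        starts = [np.asarray(s, dtype=float) for s in extra_starts]
    else:
        h0 = _init_root_height(alignment, topo.leaf_labels)
        starts = [np.concatenate([[np.log(h0)], np.zeros(len(internal_order)),
                                  [0.0] if free_r else []])]
    bounds = ([(np.log(1e-6), np.log(50.0))] + [(-14, 14)] * len(internal_order)
              + ([(np.log(_R_MIN), np.log(_R_MAX))] if free_r else []))
    best = None
    for x0 in starts:
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    h = _heights_from_params(topo, x[:n_h], internal_order)
    r = float(np.exp(x[n_h])) if free_r else 1.0
    lengths = _branch_lengths(topo, h, r, fg_nodes)
    # write fitted lengths back onto a copy of the tree
    fitted = _as_tree(write_newick_with_lengths(t, topo, lengths))
    heights = {}
    for i in range(topo.n_nodes):
        key = topo.labels[i] if topo.labels[i] else f"node_{i}"
        heights[key] = float(h[i])
    return ClockFit(
        tree_newick=fitted.as_string(schema="newick").strip(),
        node_heights=heights,
        background_rate=1.0,
        foreground=frozenset(foreground) if foreground else None,
        rate_multiplier=r,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_free_params=n_h + (1 if free_r else 0),
    ), (x, n_h)


def write_newick_with_lengths(tree: dendropy.Tree, topo: _Topology,
                              lengths: np.ndarray) -> str:
    t2 = tree.clone(depth=1)
    topo2 = _Topology(t2)
    for n in t2.postorder_node_iter():
        i = topo2.index[id(n)]
        if n.parent_node is not None:
            n.edge.length = float(lengths[i])
    return t2.as_string(schema="newick", suppress_rooting=True).strip()


def fit_global_clock(tree, alignment: MultipleAlignment,
                     model: SubstitutionModel) -> ClockFit:
    """Strict global clock: ultrametric heights, single rate (r = 1)."""
    fit, _ = _fit_clock(tree, alignment, model)
    return fit


def fit_local_clock(tree, alignment: MultipleAlignment,
                    model: SubstitutionModel, foreground_clade,
                    include_stem: bool = True,
                    null_fit_params=None) -> ClockFit:
    """Local clock: one free rate multiplier r on the foreground clade.

    The optimizer starts from the null optimum when ``null_fit_params`` is
    given (guaranteeing lnLA >= lnL0) plus an accelerated-clade start.
    """
    extra = []
    if null_fit_params is not None:
        x_null, _ = null_fit_params
        extra.append(np.concatenate([x_null, [0.0]]))
        extra.append(np.concatenate([x_null, [np.log(2.5)]]))
    fit, params = _fit_clock(tree, alignment, model,
                             foreground=set(foreground_clade),
                             include_stem=include_stem, extra_starts=extra)
    return fit


def fit_clock_pair(tree, alignment, model, foreground_clade,
                   include_stem: bool = True):
    """Convenience: fit null and (null-seeded) alternative; returns both."""
    null_fit, null_params = _fit_clock(tree, alignment, model)
    x_null, _ = null_params
    extra = [np.concatenate([x_null, [0.0]]),
             np.concatenate([x_null, [np.log(2.5)]])]
    alt_fit, _ = _fit_clock(tree, alignment, model,
                            foreground=set(foreground_clade),
                            include_stem=include_stem, extra_starts=extra)
    return null_fit, alt_fit


@dataclass
class LRTResult:
    """Likelihood-ratio test of local vs global clock."""

    lr: float
    df: int
    p_value: float
    rate_multiplier: float
    lnL0: float
    lnLA: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def lrt(fit_null: ClockFit, fit_alt: ClockFit) -> LRTResult:
    """LR = 2(lnLA - lnL0), floored at 0; p from the chi-square upper tail."""
    df = fit_alt.n_free_params - fit_null.n_free_params
    if df <= 0:
        raise ValueError(f"models not nested: df = {df}")
    lnL0, lnLA = fit_null.log_likelihood, fit_alt.log_likelihood
    if lnLA < lnL0 - 1e-4:
        raise RuntimeError(
            f"nesting violated (lnLA {lnLA:.6f} < lnL0 {lnL0:.6f}): "
            "optimizer failure")
    lr = max(0.0, 2.0 * (lnLA - lnL0))
    return LRTResult(lr=lr, df=df, p_value=float(stats.chi2.sf(lr, df)),
                     rate_multiplier=fit_alt.rate_multiplier,
                     lnL0=lnL0, lnLA=lnLA)


def lrt_from_neg_lnl(neg_lnl0: float, neg_lnl_alt: float, df: int = 1,
                     rate_multiplier: float = float("nan")) -> LRTResult:
    """LRT arithmetic from reported -lnL values (as printed in model tables)."""
    if df <= 0:
        raise ValueError(f"df must be >= 1, got {df}")
    lr = max(0.0, 2.0 * (neg_lnl0 - neg_lnl_alt))
    return LRTResult(lr=lr, df=df, p_value=float(stats.chi2.sf(lr, df)),
                     rate_multiplier=rate_multiplier,
                     lnL0=-neg_lnl0, lnLA=-neg_lnl_alt)
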