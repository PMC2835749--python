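"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: the
likelihood oracle enumerates internal-node states instead of pruning, the
covariance oracle sums pairwise root-to-MRCA paths explicitly, and the
correlation oracle applies Wright's tracing recursion instead of matrix
inversion.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from migbrain.tree import Phylogeny, read_newick
from migbrain import simulate


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip() -> Phylogeny:
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_tree(n_tips: int, rng: np.random.Generator,
                bl_range=(0.05, 2.0)) -> Phylogeny:
    """Random Yule topology with uniform random branch lengths."""
    t = simulate.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    bl = rng.uniform(*bl_range, size=t.n_nodes)
    bl[t.root] = np.nan
    return t.with_branch_lengths(bl)


# -- brute-force likelihood oracle -----------------------------------------

def enumeration_loglik(tree: Phylogeny, states: dict[str, int],
                       Q: np.ndarray, root_prior: np.ndarray) -> float:
    """Sum the joint probability over every internal-node state assignment.

    Exponential in the internal node count; only usable on tiny trees.
    """
    tip_state = {}
    for lab, nd in zip(tree.tip_labels, tree.tip_nodes):
        tip_state[int(nd)] = states[lab] - 1
    internals = [i for i in range(tree.n_nodes) if tree.children[i]]
    P = {}
    for i in range(tree.n_nodes - 1):
        P[i] = expm(Q * tree.branch_lengths[i])
    total = 0.0
    for combo in itertools.product(range(4), repeat=len(internals)):
        assign = dict(tip_state)
        for node, s in zip(internals, combo):
            assign[node] = s
        prob = root_prior[assign[tree.root]]
        for i in range(tree.n_nodes - 1):
            prob *= P[i][assign[tree.parent[i]], assign[i]]
        total += prob
    return np.log(total)


# -- brute-force covariance oracle -----------------------------------------

def bruteforce_vcv(tree: Phylogeny) -> np.ndarray:
    """Pairwise shared path lengths by explicit root-path intersection."""
    paths = {}
    for lab, nd in zip(tree.tip_labels, tree.tip_nodes):
        path = []
        i = int(nd)
        while i >= 0:
            path.append(i)
            i = int(tree.parent[i])
        paths[lab] = path[::-1]  # root ... tip
    n = tree.n_tips
    V = np.zeros((n, n))
    for a, la in enumerate(tree.tip_labels):
        for b, lb in enumerate(tree.tip_labels):
            shared = [x for x, y in zip(paths[la], paths[lb]) if x == y]
            # sum branch lengths of shared path below the root
            V[a, b] = sum(tree.branch_lengths[i] for i in shared
                          if i != tree.root)
    return V


# -- Wright tracing oracle --------------------------------------------------

def tracing_correlation(x: str, y: str, coefs: dict, exo_corr: dict) -> float:
    """Implied correlation of a standardized recursive path model by
    Wright's recursion: r(x, y) = sum over parents p of y of b_{p->y}
    r(x, p), always expanding the causally *later* variable so the
    dropped error-correlation term is genuinely zero; exogenous pairs
    read their given correlation."""
    targets = {t for _, t in coefs}
    variables = sorted({v for e in coefs for v in e} | {v for e in exo_corr
                                                        for v in e})
    incoming = {v: {s for (s, t) in coefs if t == v} for v in variables}
    topo, ready = [], [v for v in variables if not incoming[v]]
    while ready:
        v = ready.pop()
        topo.append(v)
        for w in variables:
            if v in incoming[w]:
                incoming[w].discard(v)
                if not incoming[w]:
                    ready.append(w)
    rank = {v: i for i, v in enumerate(topo)}

    def r(a: str, b: str) -> float:
        if a == b:
            return 1.0
        if b not in targets and a not in targets:
            return exo_corr.get((a, b), exo_corr.get((b, a), 0.0))
        if rank[a] > rank[b]:
            a, b = b, a
        return sum(c * r(a, s) for (s, t), c in coefs.items() if t == b)

    return r(x, y)
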