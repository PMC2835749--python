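"""Continuous-time Markov models for the correlated evolution of two
binary traits (the "independent" vs "dependent" test of discrete
characters).

Joint states are numbered 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1) with
trait 1 = migratory and trait 2 = brain_large, so that, e.g., q43 is the
rate of losing a large brain while migratory and q13 is the rate of
gaining migration while small-brained.  Simultaneous changes of both
traits (q14, q23, q32, q41) have rate zero.

* independent: each trait has its own gain and loss rate, unaffected by
  the other trait's state (4 free rates).
* dependent: all 8 single-change rates between joint states are free.

The likelihood is the pruning (post-order message passing) algorithm over
the 4-state chain; per-branch transition matrices are matrix exponentials
of the generator (scaling-and-squaring via scipy).  A numba-compiled
kernel does the tree pass, with per-node rescaling for numerical range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .tree import Phylogeny

logger = logging.getLogger(__name__)

RATE_MAX_DEFAULT = 100.0

#: dependent-model rate names, in canonical parameter-vector order
DEP_RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")
#: independent-model rate names: trait1 gain/loss, trait2 gain/loss
INDEP_RATE_NAMES = ("alpha1", "beta1", "alpha2", "beta2")

#: (from_state, to_state) zero-based indices for each dependent rate
_DEP_MOVES = {
    "q12": (0, 1), "q13": (0, 2), "q21": (1, 0), "q24": (1, 3),
    "q31": (2, 0), "q34": (2, 3), "q42": (3, 1), "q43": (3, 2),
}
#: mapping of each dependent slot to its independent-model rate: trait that
#: changes and direction (trait1 changes between states {1,2}<->{3,4} etc.)
_INDEP_EXPANSION = {
    "q13": "alpha1", "q24": "alpha1", "q31": "beta1", "q42": "beta1",
    "q12": "alpha2", "q34": "alpha2", "q21": "beta2", "q43": "beta2",
}


@dataclass
class PairedBinaryModel:
    """Rate parameterization of the joint 4-state chain."""

    kind: str                      # "independent" | "dependent"
    rates: dict[str, float]

    def __post_init__(self) -> None:
        expected = DEP_RATE_NAMES if self.kind == "dependent" else INDEP_RATE_NAMES
        if self.kind not in ("independent", "dependent"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        missing = set(expected) - set(self.rates)
        if missing:
            raise ValueError(f"missing rates: {sorted(missing)}")
        for k, v in self.rates.items():
            if v < 0:
                raise ValueError(f"rate {k} is negative: {v}")

    @property
    def rate_names(self) -> tuple[str, ...]:
        return DEP_RATE_NAMES if self.kind == "dependent" else INDEP_RATE_NAMES

    def rate_vector(self) -> np.ndarray:
        return np.array([self.rates[k] for k in self.rate_names])

    def dependent_rates(self) -> dict[str, float]:
        """The 8 joint-state rates, expanding an independent model."""
        if self.kind == "dependent":
            return dict(self.rates)
        return {q: self.rates[a] for q, a in _INDEP_EXPANSION.items()}

    def generator(self) -> np.ndarray:
        """4x4 generator matrix Q; rows sum to zero, dual changes are 0."""
        Q = np.zeros((4, 4))
        for name, (i, j) in _DEP_MOVES.items():
            Q[i, j] = self.dependent_rates()[name]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    @classmethod
    def from_vector(cls, kind: str, vec) -> "PairedBinaryModel":
        names = DEP_RATE_NAMES if kind == "dependent" else INDEP_RATE_NAMES
        return cls(kind=kind, rates=dict(zip(names, map(float, vec))))


@dataclass
class JointTraitStates:
    """Per-tip joint state in {1, 2, 3, 4} keyed by species label."""

    states: dict[str, int]

    def __post_init__(self) -> None:
        bad = {s: v for s, v in self.states.items() if v not in (1, 2, 3, 4)}
        if bad:
            raise ValueError(f"joint states must be 1..4, got {bad}")

    @classmethod
    def from_binary(cls, pairs) -> "JointTraitStates":
        """Build from BinaryTraitPair records (or any objects with
        ``species``, ``brain_large``, ``migratory``)."""
        return cls(states={
            p.species: joint_state(p.migratory, p.brain_large) for p in pairs
        })

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "JointTraitStates":
        """From a 2-column binary table with columns ``migratory`` and
        ``brain_large`` indexed (or keyed via a ``species`` column)."""
        t = df.set_index("species") if "species" in df.columns else df
        return cls(states={
            str(sp): joint_state(int(r["migratory"]), int(r["brain_large"]))
            for sp, r in t.iterrows()
        })

    def marginal(self, trait: str) -> dict[str, int]:
        if trait == "migratory":
            return {s: (v - 1) // 2 for s, v in self.states.items()}
        if trait == "brain_large":
            return {s: (v - 1) % 2 for s, v in self.states.items()}
        raise ValueError(trait)


def joint_state(migratory: int, brain_large: int) -> int:
    """State index 1..4 for a (migratory, brain_large) pair."""
    return 1 + 2 * int(migratory) + int(brain_large)


def transition_matrix(model: PairedBinaryModel, t: float) -> np.ndarray:
    """P(t) = exp(Q t): row-stochastic transition probabilities over a
    branch of length t."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0:
        return np.eye(4)
    P = expm(model.generator() * t)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


# -- pruning kernel ---------------------------------------------------------

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _prune_pass(parent, Pmats, pidx, tipL, tip_nodes, n_nodes):
    """Post-order pruning over the flat tree.

    parent: (n_nodes,) postorder parent pointers, root last (-1)
    Pmats:  (n_unique, 4, 4) transition matrices for unique branch lengths
    pidx:   (n_nodes,) index into Pmats for each node's parent branch
    tipL:   (n_tips, 4) tip partials aligned to tip_nodes
    Returns (root_partials (4,), log_scale).
    """
    L = np.ones((n_nodes, 4))
    for k in range(tip_nodes.shape[0]):
        L[tip_nodes[k]] = tipL[k]
    log_scale = 0.0
    for i in range(n_nodes - 1):
        P = Pmats[pidx[i]]
        msg = np.zeros(4)
        for a in range(4):
            acc = 0.0
            for b in range(4):
                acc += P[a, b] * L[i, b]
            msg[a] = acc
        p = parent[i]
        tot = 0.0
        for a in range(4):
            L[p, a] *= msg[a]
            tot += L[p, a]
        if i + 1 == n_nodes - 1 or parent[i + 1] != p:
            # cheap periodic rescale at the last child of each parent
            if tot > 0.0 and tot < 1e-250:
                for a in range(4):
                    L[p, a] /= tot
                log_scale += np.log(tot)
    root = L[n_nodes - 1]
    return root, log_scale


class PruningContext:
    """Precomputed tree arrays + tip partials for repeated likelihood
    evaluation (the MCMC hot path).  Branch lengths are deduplicated so a
    unit-branch-length tree needs a single matrix exponential per call."""

    def __init__(self, tree: Phylogeny, states: JointTraitStates):
        if not tree.has_branch_lengths:
            raise ValueError("tree lacks branch lengths; transform first")
        missing = [lab for lab in tree.tip_labels if lab not in states.states]
        if missing:
            raise ValueError(f"no state for tips: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        self.tree = tree
        self.parent = tree.parent.astype(np.int64)
        bl = tree.branch_lengths[:-1].astype(float)
        self.unique_bl, inv = np.unique(bl, return_inverse=True)
        self.pidx = np.concatenate([inv, [0]]).astype(np.int64)
        self.tip_nodes = tree.tip_nodes.astype(np.int64)
        tipL = np.zeros((tree.n_tips, 4))
        for k, lab in enumerate(tree.tip_labels):
            tipL[k, states.states[lab] - 1] = 1.0
        self.tipL = tipL
        self.n_nodes = tree.n_nodes

    def root_partials(self, model: PairedBinaryModel):
        Q = model.generator()
        Pmats = np.empty((len(self.unique_bl), 4, 4))
        for i, t in enumerate(self.unique_bl):
            Pmats[i] = np.eye(4) if t == 0 else expm(Q * t)
        Pmats = np.clip(Pmats, 0.0, None)
        return _prune_pass(self.parent, Pmats, self.pidx, self.tipL,
                           self.tip_nodes, self.n_nodes)

    def loglik(self, model: PairedBinaryModel,
               root_prior: np.ndarray | None = None) -> float:
        root, log_scale = self.root_partials(model)
        prior = _resolve_root_prior(root_prior, model)
        like = float(root @ prior)
        if like <= 0:
            return -np.inf
        return np.log(like) + log_scale

    def root_state_probs(self, model: PairedBinaryModel,
                         root_prior: np.ndarray | None = None) -> np.ndarray:
        """Posterior probabilities of the four root states given the tips."""
        root, _ = self.root_partials(model)
        prior = _resolve_root_prior(root_prior, model)
        w = root * prior
        tot = w.sum()
        if tot <= 0:
            return np.full(4, 0.25)
        return w / tot


def _resolve_root_prior(root_prior, model: PairedBinaryModel) -> np.ndarray:
    """Uniform by default; "equilibrium" uses the generator's stationary
    distribution."""
    if root_prior is None:
        return np.full(4, 0.25)
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            return np.full(4, 0.25)
        if root_prior == "equilibrium":
            return equilibrium_distribution(model)
        raise ValueError(f"unknown root prior {root_prior!r}")
    p = np.asarray(root_prior, dtype=float)
    if p.shape != (4,) or p.min() < 0 or not np.isclose(p.sum(), 1.0):
        raise ValueError("root prior must be a length-4 probability vector")
    return p


def equilibrium_distribution(model: PairedBinaryModel) -> np.ndarray:
    Q = model.generator()
    A = np.vstack([Q.T, np.ones(4)])
    b = np.zeros(5)
    b[4] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def loglik(tree: Phylogeny, states: JointTraitStates, model: PairedBinaryModel,
           root_prior=None) -> float:
    """Pruning log-likelihood of the tip states under the model."""
    return PruningContext(tree, states).loglik(model, root_prior)


@dataclass
class MLFitResult:
    model: PairedBinaryModel
    log_likelihood: float
    converged: bool
    n_restarts_used: int
    messages: list[str] = field(default_factory=list)


def ml_fit(tree: Phylogeny, states: JointTraitStates, kind: str,
           n_restarts: int = 5, rate_max: float = RATE_MAX_DEFAULT,
           seed: int | None = 0, root_prior=None) -> MLFitResult:
    """Maximum-likelihood rates by multi-start bounded optimization.

    Rates are optimized on a log scale (with a small floor standing in for
    zero) from several random starting points; non-convergence after all
    restarts is flagged on the result, never raised.
    """
    if tree.n_tips < 10:
        logger.warning("ml_fit on %d tips; rate estimates will be unstable",
                       tree.n_tips)
    ctx = PruningContext(tree, states)
    k = 8 if kind == "dependent" else 4
    rng = np.random.default_rng(seed)
    floor = 1e-8

    def neg_ll(log_rates):
        model = PairedBinaryModel.from_vector(kind, np.exp(log_rates))
        ll = ctx.loglik(model, root_prior)
        # keep the objective finite so numeric gradients stay defined
        return -ll if np.isfinite(ll) else 1e10

    best = None
    messages = []
    n_used = 0
    for r in range(n_restarts):
        n_used += 1
        x0 = np.log(rng.uniform(0.01, 2.0, size=k)) if r else np.full(k, np.log(0.1))
        res = minimize(neg_ll, x0, method="L-BFGS-B",
                       bounds=[(np.log(floor), np.log(rate_max))] * k)
        messages.append(str(res.message))
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = bool(best is not None and best.success and np.isfinite(best.fun))
    model = PairedBinaryModel.from_vector(kind, np.exp(best.x))
    return MLFitResult(model=model, log_likelihood=-float(best.fun),
                       converged=converged, n_restarts_used=n_used,
                       messages=messages)


def simulate_pair(tree: Phylogeny, model: PairedBinaryModel,
                  root_state: int | None = None,
                  root_prior=None, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> JointTraitStates:
    """Exact simulation of the joint chain down the tree.

    Within each branch, waiting times between single-trait flips are
    exponential with the current state's total exit rate; the flip choice
    is proportional to the outgoing rates (Gillespie).  Either a fixed
    ``root_state`` (1..4) or a draw from ``root_prior`` seeds the root.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not tree.has_branch_lengths:
        raise ValueError("tree lacks branch lengths; transform first")
    Q = model.generator()
    exit_rate = -np.diag(Q)
    if root_state is None:
        prior = _resolve_root_prior(root_prior, model)
        root_state = int(rng.choice(4, p=prior)) + 1
    if root_state not in (1, 2, 3, 4):
        raise ValueError("root_state must be in 1..4")
    state = np.zeros(tree.n_nodes, dtype=np.int64)
    state[tree.root] = root_state - 1
    for i in range(tree.n_nodes - 2, -1, -1):  # preorder
        s = state[tree.parent[i]]
        t_left = tree.branch_lengths[i]
        while exit_rate[s] > 0:
            dt = rng.exponential(1.0 / exit_rate[s])
            if dt >= t_left:
                break
            t_left -= dt
            probs = np.clip(Q[s], 0, None)
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(4, p=probs))
        state[i] = s
    out = {lab: int(state[nd]) + 1
           for lab, nd in zip(tree.tip_labels, tree.tip_nodes)}
    return JointTraitStates(states=out)
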