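"""Phylogeny container, Newick I/O, branch-length transforms and the
Brownian phylogenetic variance-covariance matrix.

The tree is stored flat (parent pointers + postorder index arrays) so the
pruning likelihood and the VCV construction can run over numpy arrays.
Polytomies are allowed everywhere; ultrametricity is never enforced (the
unit-branch-length transform deliberately breaks it on most topologies).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "transform_branch_lengths",
    "phylo_vcv",
    "lambda_transform",
    "prune_to_taxa",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid phylogeny (duplicate tips, bad lengths...)."""


@dataclass
class Phylogeny:
    """Rooted phylogeny with optional branch lengths.

    Nodes are integers 0..n_nodes-1 in postorder (every child precedes its
    parent; the root is last).  ``parent[root] == -1``.  ``branch_lengths``
    holds the length of the edge above each node; ``nan`` marks an absent
    length (distinct from zero).  Tips are the nodes with no children.
    """

    parent: np.ndarray            # (n_nodes,) int
    branch_lengths: np.ndarray    # (n_nodes,) float, nan = absent
    tip_labels: list[str]         # label of tip node i == tip_labels[tip_index]
    tip_nodes: np.ndarray         # (n_tips,) node ids of tips, aligned to tip_labels
    children: list[list[int]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not self.children:
            ch: list[list[int]] = [[] for _ in range(n)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self.children = ch
        self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def has_branch_lengths(self) -> bool:
        return not np.isnan(self.branch_lengths[:-1]).any()

    def _validate(self) -> None:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != self.n_nodes - 1:
            raise TreeValidationError("expected exactly one root, stored last in postorder")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        if any(not t for t in self.tip_labels):
            raise TreeValidationError("empty tip label")
        bl = self.branch_lengths[:-1]
        if np.any(bl[~np.isnan(bl)] < 0):
            raise TreeValidationError("negative branch length")
        for i, p in enumerate(self.parent[:-1]):
            if p <= i:
                raise TreeValidationError("node ordering is not postorder")

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> position in ``tip_labels`` / ``tip_nodes``."""
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths; requires all branch lengths present."""
        if not self.has_branch_lengths:
            raise TreeValidationError(
                "tree has absent branch lengths; apply transform_branch_lengths first"
            )
        depth = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):  # preorder = reversed postorder
            depth[i] = depth[self.parent[i]] + self.branch_lengths[i]
        return depth

    def with_branch_lengths(self, bl: np.ndarray) -> "Phylogeny":
        return Phylogeny(
            parent=self.parent.copy(),
            branch_lengths=np.asarray(bl, dtype=float).copy(),
            tip_labels=list(self.tip_labels),
            tip_nodes=self.tip_nodes.copy(),
        )


@dataclass
class PhyloCovariance:
    """Brownian-motion tip covariance: V[i, j] = depth of the MRCA of tips
    i and j above the root; diagonal = total tip depths."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValueError("covariance shape does not match label count")

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        pos = {lab: i for i, lab in enumerate(self.labels)}
        idx = np.array([pos[lab] for lab in labels])
        return PhyloCovariance(labels=list(labels), matrix=self.matrix[np.ix_(idx, idx)])


# -- Newick I/O -------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.postorder_node_iter())
    order = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    bl = np.full(n, np.nan)
    tip_labels: list[str] = []
    tip_nodes: list[int] = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = order[id(nd.parent_node)]
            if nd.edge.length is not None:
                bl[i] = float(nd.edge.length)
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            tip_labels.append(label)
            tip_nodes.append(i)
    return Phylogeny(
        parent=parent,
        branch_lengths=bl,
        tip_labels=tip_labels,
        tip_nodes=np.asarray(tip_nodes, dtype=np.int64),
    )


def read_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree from a string.

    Quoted labels and bracketed comments are tolerated; duplicate tip labels
    raise :class:`TreeValidationError`; syntax errors raise
    :class:`NewickError` naming the offending position when known.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise NewickError(f"malformed Newick{where}: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise NewickError("malformed Newick: empty tree")
    return _from_dendropy(dtree)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def _fmt_bl(x: float) -> str:
    s = f"{x:.10g}"
    return s


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick with 10-significant-digit branch lengths."""
    parts: list[str] = [""] * tree.n_nodes
    label = {int(nd): lab for nd, lab in zip(tree.tip_nodes, tree.tip_labels)}
    for i in range(tree.n_nodes):
        if tree.children[i]:
            body = "(" + ",".join(parts[c] for c in tree.children[i]) + ")"
        else:
            body = label[i]
        if i != tree.root and not np.isnan(tree.branch_lengths[i]):
            body += f":{_fmt_bl(tree.branch_lengths[i])}"
        parts[i] = body
    return parts[tree.root] + ";"


def write_newick_file(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- transforms -------------------------------------------------------------

def _descendant_tip_counts(tree: Phylogeny) -> np.ndarray:
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    counts[tree.tip_nodes] = 1
    for i in range(tree.n_nodes - 1):
        counts[tree.parent[i]] += counts[i]
    return counts


def transform_branch_lengths(tree: Phylogeny, method: str) -> Phylogeny:
    """Assign branch lengths by rule rather than data.

    ``unit``
        every branch gets length 1 (the headline analysis convention).
    ``grafen``
        node height = number of descendant tips - 1 (Grafen's rho = 1),
        rescaled so root-to-tip depth is 1; tips contemporaneous at height 0.
    ``pagel``
        node height = number of internal nodes in the node's subtree
        (itself included); tips at height 0, so tips are contemporaneous and
        each branch spans at least one unit between internal levels.
    """
    if method == "unit":
        bl = np.ones(tree.n_nodes)
        bl[tree.root] = np.nan
        return tree.with_branch_lengths(bl)

    heights = np.zeros(tree.n_nodes)
    if method == "grafen":
        counts = _descendant_tip_counts(tree)
        heights = (counts - 1).astype(float)
        root_h = heights[tree.root]
        if root_h > 0:
            heights /= root_h
    elif method == "pagel":
        internal = np.zeros(tree.n_nodes, dtype=np.int64)
        for i in range(tree.n_nodes):
            if tree.children[i]:
                internal[i] += 1
        for i in range(tree.n_nodes - 1):
            if tree.children[i]:
                internal[tree.parent[i]] += internal[i]
        heights = internal.astype(float)
    else:
        raise ValueError(f"unknown branch-length method: {method!r}")

    bl = np.full(tree.n_nodes, np.nan)
    for i in range(tree.n_nodes - 1):
        bl[i] = heights[tree.parent[i]] - heights[i]
    return tree.with_branch_lengths(bl)


# -- covariance -------------------------------------------------------------

def phylo_vcv(tree: Phylogeny) -> PhyloCovariance:
    """Brownian tip variance-covariance matrix of the tree.

    V[i, j] is the root-to-MRCA path length shared by tips i and j;
    V[i, i] is the total depth of tip i.
    """
    depth = tree.node_depths()  # raises if lengths absent
    n_tips = tree.n_tips
    V = np.zeros((n_tips, n_tips))
    tip_pos = np.full(tree.n_nodes, -1, dtype=np.int64)
    tip_pos[tree.tip_nodes] = np.arange(n_tips)

    # tips under each node, built bottom-up; cross-child pairs share that node
    under: list[np.ndarray | None] = [None] * tree.n_nodes
    for i in range(tree.n_nodes):
        if not tree.children[i]:
            under[i] = np.array([tip_pos[i]])
            continue
        kids = [under[c] for c in tree.children[i]]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                V[np.ix_(kids[a], kids[b])] = depth[i]
                V[np.ix_(kids[b], kids[a])] = depth[i]
        under[i] = np.concatenate(kids)
        for c in tree.children[i]:
            under[c] = None
    V[np.arange(n_tips), np.arange(n_tips)] = depth[tree.tip_nodes]
    return PhyloCovariance(labels=list(tree.tip_labels), matrix=V)


def lambda_transform(V: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: scale off-diagonal covariances, keep variances."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M = V.matrix * lam
    np.fill_diagonal(M, np.diag(V.matrix))
    return PhyloCovariance(labels=list(V.labels), matrix=M)


# -- pruning ---------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep: list[str]) -> Phylogeny:
    """Restrict the tree to a subset of tips.

    Degree-2 internal nodes created by the pruning are collapsed and their
    branch lengths summed (nan-propagating: collapsing an absent length
    keeps the result absent).
    """
    keep_set = set(keep)
    missing = keep_set - set(tree.tip_labels)
    if missing:
        raise TreeValidationError(f"tips not in tree: {sorted(missing)}")
    if len(keep_set) < 2:
        raise TreeValidationError("cannot prune to fewer than 2 tips")
    dtree = dendropy.Tree.get(
        data=write_newick(tree), schema="newick", preserve_underscores=True
    )
    taxa = [t for t in dtree.taxon_namespace if t.label in keep_set]
    dtree.retain_taxa(taxa)
    # dendropy may leave a degree-1 root edge; collapse it
    seed = dtree.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        if child.is_leaf():
            break
        for gc in list(child.child_nodes()):
            child.remove_child(gc)
            seed.add_child(gc)
            if gc.edge.length is not None and child.edge.length is not None:
                gc.edge.length += child.edge.length
        seed.remove_child(child)
    return _from_dendropy(dtree)
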