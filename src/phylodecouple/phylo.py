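"""Rooted time-tree container and tree-derived quantities.

The :class:`Phylogeny` is the hub of the package: it stores a rooted tree
with branch lengths in millions of years (My) as flat integer/float arrays
(parent pointers, per-node branch lengths, postorder) and provides the
quantities every comparative method downstream needs — node ages, patristic
distances, and the Brownian-motion phylogenetic covariance matrix.

Newick reading/writing is delegated to :mod:`dendropy`; the array form is
rebuilt deterministically from the parsed tree so that node indices, and
therefore every seeded computation, are reproducible for a given Newick
string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "read_newick",
    "write_newick",
    "node_ages",
    "patristic_distances",
    "phylo_covariance",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix (zero diagonal).

    Used both for pairwise Procrustes distances between species mean shapes
    and for patristic (phylogenetic) distances between tips.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(
                f"matrix shape {v.shape} does not match {n} labels"
            )
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        """Return a copy with rows/columns permuted to ``labels``."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major, i > j) as a flat vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


class PhylogenyError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree over ``n_nodes`` nodes with branch lengths in My.

    Node indexing convention: tips are ``0 .. n_tips-1`` in the order of
    ``tip_labels``; internal nodes follow; the root is ``root``. ``parent``
    is -1 at the root; ``branch_lengths[i]`` is the length of the branch
    subtending node ``i`` (0.0 at the root).
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray          # (n_nodes,) int, -1 at root
    branch_lengths: np.ndarray  # (n_nodes,) float, My
    root: int

    children: list[list[int]] = field(init=False, repr=False)
    postorder: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        n = self.parent.size
        if self.branch_lengths.size != n:
            raise PhylogenyError("parent/branch_lengths size mismatch")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise PhylogenyError("tip labels are not unique")
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise PhylogenyError("tree must have exactly one root")
        if (self.branch_lengths[np.arange(n) != self.root] <= 0).any():
            raise PhylogenyError("all non-root branch lengths must be > 0")
        self.children = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        if len(order) != n:
            raise PhylogenyError("tree is not connected")
        self.postorder = np.array(order[::-1], dtype=np.int64)

    # -- basic structure ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def is_bifurcating(self) -> bool:
        return all(
            len(c) in (0, 2) for c in self.children
        )

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths, in My."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:  # preorder
            if v != self.root:
                d[v] = d[self.parent[v]] + self.branch_lengths[v]
        return d

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        tip_depths = self.depths()[: self.n_tips]
        span = tip_depths.max() - tip_depths.min()
        return bool(span <= rtol * max(tip_depths.max(), 1e-300))

    def prune_to(self, taxa: list[str] | set[str]) -> "Phylogeny":
        """Restrict the tree to ``taxa``, suppressing unary nodes."""
        keep = set(taxa)
        missing = keep - set(self.tip_labels)
        if missing:
            raise PhylogenyError(f"taxa not in tree: {sorted(missing)}")
        d = _to_dendropy(self)
        d.retain_taxa_with_labels(sorted(keep))
        return _from_dendropy(d)

    def newick(self) -> str:
        return write_newick(self)


# -- Newick I/O (dendropy-backed) -----------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string with branch lengths into a :class:`Phylogeny`.

    Internal node labels are ignored (with a warning); a missing branch
    length on any non-root edge is an error.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise PhylogenyError(f"malformed Newick: {exc}") from exc
    if any(
        nd.label is not None for nd in dtree.preorder_internal_node_iter()
    ):
        warnings.warn("internal node labels ignored", stacklevel=2)
    return _from_dendropy(dtree)


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    tips = [lf for lf in dtree.leaf_node_iter()]
    labels = []
    for lf in tips:
        if lf.taxon is None or lf.taxon.label is None:
            raise PhylogenyError("unlabelled tip")
        labels.append(lf.taxon.label)
    order = np.argsort(labels, kind="stable")
    tips = [tips[i] for i in order]
    labels = [labels[i] for i in order]
    node_index: dict[int, int] = {id(lf): i for i, lf in enumerate(tips)}
    nxt = len(tips)
    for nd in dtree.postorder_internal_node_iter():
        node_index[id(nd)] = nxt
        nxt += 1
    n = nxt
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    root = node_index[id(dtree.seed_node)]
    for nd in dtree.preorder_node_iter():
        i = node_index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = node_index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise PhylogenyError(
                    f"missing branch length above node {nd.taxon.label if nd.taxon else i}"
                )
            blen[i] = float(nd.edge.length)
    return Phylogeny(tuple(labels), parent, blen, root)


def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {tree.root: dtree.seed_node}
    stack = [tree.root]
    while stack:
        v = stack.pop()
        for c in tree.children[v]:
            child = nodes[v].new_child(edge_length=float(tree.branch_lengths[c]))
            nodes[c] = child
            stack.append(c)
        if not tree.children[v]:
            nodes[v].taxon = taxa.new_taxon(tree.tip_labels[v])
    return dtree


def write_newick(tree: Phylogeny) -> str:
    d = _to_dendropy(tree)
    return d.as_string(schema="newick", suppress_rooting=True).strip()


# -- tree-derived quantities ----------------------------------------------


def node_ages(tree: Phylogeny, rtol: float = 1e-6) -> np.ndarray:
    """Ages (My before present) per node; requires an ultrametric tree.

    Tips are at age 0 and the root at the maximum root-to-tip path length.
    """
    if not tree.is_ultrametric(rtol=rtol):
        raise PhylogenyError("tree is not ultrametric; node ages undefined")
    depths = tree.depths()
    ages = depths[: tree.n_tips].max() - depths
    ages[: tree.n_tips] = 0.0
    return ages


def patristic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Sum of branch lengths along the tip-to-tip path, for all tip pairs."""
    depths = tree.depths()
    mrca_depth = _mrca_depths(tree, depths)
    tip_depth = depths[: tree.n_tips]
    d = tip_depth[:, None] + tip_depth[None, :] - 2.0 * mrca_depth
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return DistanceMatrix(tree.tip_labels, (d + d.T) / 2.0)


def phylo_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair.

    Rows/columns follow ``tree.tip_labels``; the diagonal holds root-to-tip
    depths. Symmetric positive semi-definite by construction.
    """
    depths = tree.depths()
    C = _mrca_depths(tree, depths)
    np.fill_diagonal(C, depths[: tree.n_tips])
    return C


def _mrca_depths(tree: Phylogeny, depths: np.ndarray) -> np.ndarray:
    """Matrix of root-to-MRCA depths over tip pairs (diagonal left at 0)."""
    n = tree.n_tips
    out = np.zeros((n, n))
    # Postorder accumulation of descendant-tip sets; cross-child pairs
    # coalesce exactly at the current node.
    tipsets: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if not tree.children[v]:
            tipsets[v] = np.array([v], dtype=np.int64)
            continue
        kids = [tipsets.pop(c) for c in tree.children[v]]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                out[np.ix_(kids[a], kids[b])] = depths[v]
                out[np.ix_(kids[b], kids[a])] = depths[v]
        tipsets[v] = np.concatenate(kids)
    return out
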