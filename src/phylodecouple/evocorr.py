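"""Evolutionary correlations of trait axes on a phylogeny.

Implements the contrast-based machinery for testing whether two trait
complexes evolved in a correlated fashion: phylogenetically independent
contrasts (Felsenstein's pruning recursion), their through-origin Pearson
correlation, Brownian-motion trait simulation, a simulated null
distribution of contrast correlations between independent traits, and a
phylogenetic two-block partial least squares (pPLS) fit measuring
morphological integration between two multivariate blocks.

Under Brownian motion the standardized contrasts are i.i.d. with mean
zero, which licenses ordinary correlation — computed through the origin,
with ``df = n_contrasts - 1`` — as the test statistic for correlated
evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phylo import Phylogeny, PhylogenyError, phylo_covariance

__all__ = [
    "PICSet",
    "CorrelationResult",
    "NullDistribution",
    "PLSResult",
    "pic",
    "pic_correlation",
    "bm_simulate",
    "null_correlations",
    "phylo_pls",
]


@dataclass(frozen=True)
class PICSet:
    """Standardized independent contrasts for one trait.

    ``node_order`` records the internal node index (in tree coordinates)
    each contrast belongs to, in deterministic postorder, so two PICSets
    from the same tree are comparable element-wise.
    """

    contrasts: np.ndarray
    node_order: np.ndarray

    def __len__(self) -> int:
        return self.contrasts.size


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    df: int


@dataclass(frozen=True)
class NullDistribution:
    """Null correlations between independent BM trait pairs."""

    r_values: np.ndarray

    @property
    def min(self) -> float:
        return float(self.r_values.min())

    @property
    def max(self) -> float:
        return float(self.r_values.max())

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        q = np.quantile(self.r_values, [lo, 1.0 - lo])
        return float(q[0]), float(q[1])

    def contains(self, r: float, level: float = 0.95) -> bool:
        lo, hi = self.central_interval(level)
        return lo <= r <= hi


@dataclass(frozen=True)
class PLSResult:
    r_pls: float
    p: float
    u: np.ndarray       # left singular vector (block 1 loadings)
    v: np.ndarray       # right singular vector (block 2 loadings)
    scores1: np.ndarray
    scores2: np.ndarray
    n_permutations: int
    seed: int


def _pic_order(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic bifurcating postorder with child ordering.

    Children of each internal node are ordered so the child whose
    lexicographically smallest descendant tip label sorts first comes
    first; the contrast is first-child minus second-child. Returns
    (internal nodes in postorder, left child, right child).
    """
    smallest: list[str | None] = [None] * tree.n_nodes
    for v in tree.postorder:
        if not tree.children[v]:
            smallest[v] = tree.tip_labels[v]
        else:
            smallest[v] = min(smallest[c] for c in tree.children[v])
    internal, left, right = [], [], []
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        if len(kids) != 2:
            raise PhylogenyError(
                f"node {v} has {len(kids)} children; contrasts require a "
                "bifurcating tree"
            )
        a, b = sorted(kids, key=lambda c: smallest[c])
        internal.append(v)
        left.append(a)
        right.append(b)
    return (
        np.array(internal, dtype=np.int64),
        np.array(left, dtype=np.int64),
        np.array(right, dtype=np.int64),
    )


def pic(tree: Phylogeny, trait: dict[str, float]) -> PICSet:
    """Phylogenetically independent contrasts of one trait.

    At each internal node with child values ``x_i, x_j`` on adjusted
    branch lengths ``v_i, v_j`` the standardized contrast is
    ``(x_i - x_j) / sqrt(v_i + v_j)``; the node is assigned the
    inverse-variance-weighted mean and its parent branch is lengthened by
    ``v_i v_j / (v_i + v_j)``.
    """
    missing = [l for l in tree.tip_labels if l not in trait]
    if missing:
        raise ValueError(f"missing trait value for tips: {missing}")
    x = np.zeros(tree.n_nodes)
    x[: tree.n_tips] = [trait[l] for l in tree.tip_labels]
    return _pic_from_tip_values(tree, x[: tree.n_tips])


def _pic_from_tip_values(tree: Phylogeny, tip_values: np.ndarray) -> PICSet:
    internal, left, right = _pic_order(tree)
    x = np.zeros(tree.n_nodes)
    x[: tree.n_tips] = tip_values
    v = tree.branch_lengths.astype(float).copy()
    contrasts = np.empty(internal.size)
    for k in range(internal.size):
        nd, a, b = internal[k], left[k], right[k]
        va, vb = v[a], v[b]
        contrasts[k] = (x[a] - x[b]) / np.sqrt(va + vb)
        x[nd] = (x[a] / va + x[b] / vb) / (1.0 / va + 1.0 / vb)
        v[nd] += va * vb / (va + vb)
    return PICSet(contrasts, internal)


def pic_correlation(x: PICSet, y: PICSet) -> CorrelationResult:
    """Through-origin Pearson correlation of two contrast sets.

    ``r = Σ x_i y_i / sqrt(Σ x_i² Σ y_i²)``, df = n_contrasts − 1,
    two-tailed p from the t distribution.
    """
    if len(x) != len(y) or not np.array_equal(x.node_order, y.node_order):
        raise ValueError("contrast sets come from different trees/orders")
    sx2 = float(np.dot(x.contrasts, x.contrasts))
    sy2 = float(np.dot(y.contrasts, y.contrasts))
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("zero-variance contrasts; correlation undefined")
    r = float(np.dot(x.contrasts, y.contrasts) / np.sqrt(sx2 * sy2))
    df = len(x) - 1
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_ * r_))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r, p, df)


def bm_simulate(
    tree: Phylogeny,
    rate: float,
    root_state: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Simulate one Brownian-motion trait: child = parent + N(0, rate·t)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    x = np.empty(tree.n_nodes)
    x[tree.root] = root_state
    for v in tree.postorder[::-1]:
        if v != tree.root:
            x[v] = x[tree.parent[v]] + rng.normal(
                0.0, np.sqrt(rate * tree.branch_lengths[v])
            )
    return {l: float(x[i]) for i, l in enumerate(tree.tip_labels)}


def _bm_tip_values(
    tree: Phylogeny, rate: float, rng: np.random.Generator, n_reps: int
) -> np.ndarray:
    """Vectorized BM simulation: (n_reps, n_tips) tip values, root at 0."""
    incr = rng.standard_normal((n_reps, tree.n_nodes)) * np.sqrt(
        rate * tree.branch_lengths
    )
    x = np.zeros((n_reps, tree.n_nodes))
    for v in tree.postorder[::-1]:
        if v != tree.root:
            x[:, v] = x[:, tree.parent[v]] + incr[:, v]
    return x[:, : tree.n_tips]


def null_correlations(
    tree: Phylogeny, n_pairs: int = 1000, seed: int = 0
) -> NullDistribution:
    """Null distribution of through-origin PIC correlations.

    Simulates ``n_pairs`` independent pairs of unit-rate BM traits on the
    tree and correlates the contrasts within each pair; the extreme range
    of the resulting r values is the reference band against which observed
    evolutionary correlations are judged.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    xs = _bm_tip_values(tree, 1.0, rng, n_pairs)
    ys = _bm_tip_values(tree, 1.0, rng, n_pairs)
    rs = np.empty(n_pairs)
    for k in range(n_pairs):
        cx = _pic_from_tip_values(tree, xs[k])
        cy = _pic_from_tip_values(tree, ys[k])
        rs[k] = np.dot(cx.contrasts, cy.contrasts) / np.sqrt(
            np.dot(cx.contrasts, cx.contrasts)
            * np.dot(cy.contrasts, cy.contrasts)
        )
    return NullDistribution(rs)


def _inv_sqrt(C: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetric inverse square root, eigenvalues floored at ``floor``."""
    w, Q = np.linalg.eigh(C)
    if w.max() <= 0:
        raise np.linalg.LinAlgError("covariance matrix is not positive")
    w = np.maximum(w, floor)
    return (Q / np.sqrt(w)) @ Q.T


def phylo_pls(
    block1: np.ndarray,
    block2: np.ndarray,
    tree: Phylogeny,
    n_permutations: int = 999,
    seed: int = 0,
) -> PLSResult:
    """Phylogenetic two-block partial least squares.

    Finds, via SVD of the evolutionary (phylogenetically corrected)
    cross-covariance between the two blocks, the paired axes of most
    covariance; ``r_pls`` is the Pearson correlation of the species
    scores on those axes after transforming the data by the inverse
    square root of the phylogenetic covariance. Significance is assessed
    by permuting species rows of the transformed second block (add-one
    permutation p-value).
    """
    X1 = np.atleast_2d(np.asarray(block1, dtype=float))
    X2 = np.atleast_2d(np.asarray(block2, dtype=float))
    n = tree.n_tips
    if X1.shape[0] != n or X2.shape[0] != n:
        raise ValueError("blocks must have one row per tree tip")
    if n < 3:
        raise ValueError("need at least 3 species")
    C = phylo_covariance(tree)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular phylogenetic covariance") from exc
    one = np.ones((n, 1))
    denom = float((one.T @ Cinv @ one)[0, 0])
    a1 = (one.T @ Cinv @ X1) / denom
    a2 = (one.T @ Cinv @ X2) / denom
    X1c = X1 - one @ a1
    X2c = X2 - one @ a2
    R12 = X1c.T @ Cinv @ X2c / (n - 1)
    if not np.any(np.abs(R12) > 0):
        raise ValueError("zero cross-covariance between blocks")
    U, s, Vt = np.linalg.svd(R12, full_matrices=False)
    u, v = U[:, 0], Vt[0, :]
    # reproducible axis orientation
    if u[np.argmax(np.abs(u))] < 0:
        u, v = -u, -v
    Cih = _inv_sqrt(C)
    T1 = Cih @ X1c
    T2 = Cih @ X2c
    s1 = T1 @ u
    s2 = T2 @ v
    r_obs = _pearson(s1, s2)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        T2p = T2[perm]
        Rp = T1.T @ T2p / (n - 1)
        Up, _, Vtp = np.linalg.svd(Rp, full_matrices=False)
        rp = abs(_pearson(T1 @ Up[:, 0], T2p @ Vtp[0, :]))
        if rp >= abs(r_obs):
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return PLSResult(
        r_pls=abs(r_obs), p=p, u=u, v=v, scores1=s1, scores2=s2,
        n_permutations=n_permutations, seed=seed,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))
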