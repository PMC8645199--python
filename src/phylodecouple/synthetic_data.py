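"""Synthetic radiations: trees, coupled jaw traits, and landmark datasets.

The generator emulates the statistical structure of a lacustrine cichlid
radiation: an ultrametric pure-birth tree (~10 My root age, up to a few
hundred tips), species-level multivariate trait evolution under Brownian
motion with a configurable cross-jaw correlation and optional
branch/epoch-specific rate scalars, and per-specimen landmark
configurations deformed along the trait axes with i.i.d. digitization
noise and random rigid motions.

Scenarios
---------
``coupled``         the two jaw blocks share a high increment correlation.
``decoupled``       increments of the two blocks are independent.
``late_decoupled``  increments are correlated on branch segments older
                    than ``change_age`` and independent (or weakly
                    correlated) on younger segments; branches crossing the
                    change age are split at it.
``shifted_clade``   a named clade evolves with multiplied increment
                    variance in both blocks (a planted rate shift).

Coupling acts on the Brownian increments (the evolutionary process), not
on tip values: this is exactly the "evolutionary correlation" that the
contrast-based tests downstream are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo import Phylogeny, node_ages

__all__ = [
    "Scenario",
    "make_scenario",
    "simulate_tree",
    "simulate_jaw_traits",
    "simulate_branch_rates",
    "traits_to_landmarks",
    "premaxilla_template",
    "lpj_half_template",
    "deformation_basis",
]


@dataclass(frozen=True)
class Scenario:
    """A named coupling scenario for the two-jaw generator."""

    name: str = "decoupled"
    cross_block_correlation: float = 0.0
    rho_old: float | None = None
    rho_young: float | None = None
    change_age: float | None = None
    planted_shifts: tuple[tuple[frozenset, float], ...] = ()
    n_tips: int = 234
    root_age: float = 10.0
    n_specimens_per_species: int = 5
    specimen_noise_sd: float = 0.005
    rates_a: tuple[float, float, float] = (5e-5, 5e-5, 5e-5)
    rates_b: tuple[float, float, float] = (5e-4, 5e-4, 5e-4)
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in (self.cross_block_correlation, self.rho_old, self.rho_young):
            if rho is not None and abs(rho) > 1:
                raise ValueError("|cross-block correlation| must be <= 1")
        if any(s <= 0 for _, s in self.planted_shifts):
            raise ValueError("planted shift scalars must be > 0")
        if self.specimen_noise_sd < 0:
            raise ValueError("specimen noise sd must be >= 0")


_PRESETS = {
    "coupled": dict(cross_block_correlation=0.9),
    "decoupled": dict(cross_block_correlation=0.0),
    "late_decoupled": dict(
        cross_block_correlation=0.0, rho_old=0.8, rho_young=0.0, change_age=2.0
    ),
    "shifted_clade": dict(cross_block_correlation=0.0),
}


def make_scenario(name: str, **overrides) -> Scenario:
    """Build a preset scenario, overriding any field."""
    if name not in _PRESETS:
        raise ValueError(f"unknown scenario {name!r}; choose {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return Scenario(name=name, **kw)


class _Lineage:
    __slots__ = ("start", "children")

    def __init__(self, start: float) -> None:
        self.start = start
        self.children: list[tuple[_Lineage, float]] = []  # (child, split t)


def simulate_tree(n_tips: int, root_age: float = 10.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree rescaled to ``root_age`` exactly.

    Deterministic for a given seed; tips are labelled ``sp0001 ...``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    rng = np.random.default_rng(seed)
    root = _Lineage(0.0)
    active = []
    for _ in range(2):
        child = _Lineage(0.0)
        root.children.append((child, 0.0))
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent_lin = active.pop(k)
        for _ in range(2):
            child = _Lineage(t)
            parent_lin.children.append((child, t))
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    scale = root_age / t_end
    # flatten into Phylogeny arrays: tips first in a stable left-to-right
    # traversal order so labels are deterministic
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    next_tip = 0
    next_internal = n_tips

    def assign(lin: _Lineage) -> int:
        nonlocal next_tip, next_internal
        if not lin.children:
            idx = next_tip
            next_tip += 1
            blen[idx] = (t_end - lin.start) * scale
            return idx
        kid_ids = [assign(c) for c, _ in lin.children]
        idx = next_internal
        next_internal += 1
        split_t = lin.children[0][1]
        blen[idx] = (split_t - lin.start) * scale
        for kid in kid_ids:
            parent[kid] = idx
        return idx

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n_tips + 1000))
    try:
        root_idx = assign(root)
    finally:
        sys.setrecursionlimit(old_limit)
    blen[root_idx] = 0.0
    labels = tuple(f"sp{i + 1:04d}" for i in range(n_tips))
    return Phylogeny(labels, parent, blen, root_idx)


def simulate_jaw_traits(
    tree: Phylogeny, scenario: Scenario
) -> tuple[np.ndarray, np.ndarray]:
    """Joint BM simulation of two 3-axis trait blocks on the tree.

    Returns ``(block_a, block_b)``, each of shape (n_tips, 3), rows in
    ``tree.tip_labels`` order. Matched axes (A1-B1, A2-B2, A3-B3) share
    the scenario's cross-block increment correlation; planted clade
    shifts multiply the increment variance of every branch inside the
    clade (both blocks).
    """
    rng = np.random.default_rng(scenario.seed)
    ages = node_ages(tree)
    rho_default = scenario.cross_block_correlation
    clade_mult = _clade_multipliers(tree, scenario)
    xa = np.zeros((tree.n_nodes, 3))
    xb = np.zeros((tree.n_nodes, 3))
    ra = np.asarray(scenario.rates_a)
    rb = np.asarray(scenario.rates_b)
    for v in tree.postorder[::-1]:  # preorder: parents before children
        if v == tree.root:
            continue
        p = tree.parent[v]
        da = np.zeros(3)
        db = np.zeros(3)
        for older, younger in _segments_for(
            ages[p], ages[v], scenario.change_age
        ):
            dt = older - younger
            if scenario.change_age is not None:
                # segment lies entirely on one side of the change age
                old_side = (older + younger) / 2.0 > scenario.change_age
                rho = scenario.rho_old if old_side else scenario.rho_young
                rho = rho_default if rho is None else rho
            else:
                rho = rho_default
            z1 = rng.standard_normal(3)
            z2 = rng.standard_normal(3)
            zb = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
            m = clade_mult[v]
            da += np.sqrt(ra * dt * m) * z1
            db += np.sqrt(rb * dt * m) * zb
        xa[v] = xa[p] + da
        xb[v] = xb[p] + db
    return xa[: tree.n_tips], xb[: tree.n_tips]


def _segments_for(
    older: float, younger: float, change_age: float | None
) -> list[tuple[float, float]]:
    if change_age is not None and older > change_age > younger:
        return [(older, change_age), (change_age, younger)]
    return [(older, younger)]


def _clade_multipliers(tree: Phylogeny, scenario: Scenario) -> np.ndarray:
    mult = np.ones(tree.n_nodes)
    if not scenario.planted_shifts:
        return mult
    label_to_tip = {l: i for i, l in enumerate(tree.tip_labels)}
    for tip_set, scalar in scenario.planted_shifts:
        tips = {label_to_tip[t] for t in tip_set}
        mrca = _mrca(tree, tips)
        for v in _clade_nodes(tree, mrca):
            if v != mrca:  # scale the branches *within* the clade
                mult[v] *= scalar
    return mult


def _mrca(tree: Phylogeny, tips: set[int]) -> int:
    paths = []
    for t in tips:
        path = []
        v = t
        while v != -1:
            path.append(v)
            v = tree.parent[v]
        paths.append(path[::-1])
    mrca = tree.root
    for nodes in zip(*paths):
        if len(set(nodes)) == 1:
            mrca = nodes[0]
        else:
            break
    return mrca


def _clade_nodes(tree: Phylogeny, node: int) -> list[int]:
    out = []
    stack = [node]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(tree.children[v])
    return out


def simulate_branch_rates(
    tree: Phylogeny, scenario: Scenario, seed: int | None = None
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-branch relative evolutionary rates for the two jaws.

    Rates are log-normal with unit median; the log-rates of the two jaws
    share the scenario's coupling: correlation ``rho_old`` for branches
    whose midpoint age is older than ``change_age`` and ``rho_young`` for
    younger branches (falling back to the scenario's flat cross-block
    correlation when no change age is set). Keyed by child-node branch id.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    ages = node_ages(tree)
    ra: dict[int, float] = {}
    rb: dict[int, float] = {}
    sd = 0.5  # log-rate spread
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        mid = (ages[tree.parent[v]] + ages[v]) / 2.0
        if scenario.change_age is not None:
            rho = scenario.rho_old if mid > scenario.change_age else scenario.rho_young
            rho = scenario.cross_block_correlation if rho is None else rho
        else:
            rho = scenario.cross_block_correlation
        z1 = rng.standard_normal()
        z2 = rng.standard_normal()
        zb = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
        ra[v] = float(np.exp(sd * z1))
        rb[v] = float(np.exp(sd * zb))
    return ra, rb


# -- landmark templates and deformation -----------------------------------


def premaxilla_template() -> np.ndarray:
    """Centered 4-landmark 2-D quadrilateral standing in for a premaxilla."""
    pts = np.array(
        [[0.0, 0.0], [1.0, 0.1], [0.9, 0.8], [0.1, 0.6]]
    )
    return pts - pts.mean(axis=0)


def lpj_half_template(n_midline: int = 9, n_paired: int = 12) -> tuple[
    np.ndarray, np.ndarray, np.ndarray
]:
    """Centered 3-D half-configuration standing in for a pharyngeal jaw.

    Returns (coords, midline index array, paired index array); midline
    landmarks lie in the x=0 plane, paired landmarks at x < 0 (left
    side). Sized 21 landmarks by default for speed; configurable up to
    the anatomical 27 (12 midline + 15 paired).
    """
    rng = np.random.default_rng(1234)  # fixed template geometry
    s = np.linspace(-1.0, 1.0, n_midline)
    midline = np.column_stack(
        [np.zeros(n_midline), s, 0.25 * (1 - s**2)]
    )
    paired = np.column_stack(
        [
            -(0.3 + 0.5 * rng.random(n_paired)),
            rng.uniform(-1.0, 1.0, n_paired),
            rng.uniform(-0.1, 0.3, n_paired),
        ]
    )
    coords = np.vstack([midline, paired])
    coords = coords - coords.mean(axis=0)
    return (
        coords,
        np.arange(n_midline),
        np.arange(n_midline, n_midline + n_paired),
    )


def deformation_basis(
    template: np.ndarray, n_axes: int = 3, seed: int = 99
) -> np.ndarray:
    """Orthonormal deformation vectors over the flattened template.

    Columns are unit-norm, mutually orthogonal, and orthogonal to rigid
    translations of the configuration (so deformations are genuine shape
    changes, not shifts).
    """
    k, d = template.shape
    rng = np.random.default_rng(seed)
    # translation directions to project out
    trans = np.zeros((k * d, d))
    for j in range(d):
        trans[j::d, j] = 1.0
    raw = rng.standard_normal((k * d, n_axes))
    raw -= trans @ np.linalg.lstsq(trans, raw, rcond=None)[0]
    q, _ = np.linalg.qr(raw)
    return q[:, :n_axes]


def traits_to_landmarks(
    trait_scores: np.ndarray,
    template: np.ndarray,
    basis: np.ndarray,
    scenario: Scenario,
    species_labels: list[str] | tuple[str, ...],
    seed: int | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Landmark configurations for every specimen of every species.

    Species mean configuration = template + basis @ scores; each specimen
    adds i.i.d. Gaussian coordinate noise and a random rigid motion plus
    scale, to exercise the alignment step downstream. Returns
    ``(coords, specimen_ids, species_ids)`` with ``coords`` of shape
    (n_specimens_total, K, dims).
    """
    template = np.asarray(template, dtype=float)
    k, d = template.shape
    basis = np.asarray(basis, dtype=float)
    scores = np.atleast_2d(np.asarray(trait_scores, dtype=float))
    if basis.shape[0] != k * d or basis.shape[1] != scores.shape[1]:
        raise ValueError("deformation basis does not match template/scores")
    gram = basis.T @ basis
    if np.abs(gram - np.eye(basis.shape[1])).max() > 1e-8:
        raise ValueError("deformation basis columns are not orthonormal")
    rng = np.random.default_rng(scenario.seed + 7919 if seed is None else seed)
    per = scenario.n_specimens_per_species
    coords = np.empty((scores.shape[0] * per, k, d))
    specimen_ids, species_ids = [], []
    row = 0
    for s, label in enumerate(species_labels):
        mean_cfg = template + (basis @ scores[s]).reshape(k, d)
        for j in range(per):
            cfg = mean_cfg + rng.normal(0.0, scenario.specimen_noise_sd, (k, d))
            cfg = _random_rigid_motion(cfg, rng)
            coords[row] = cfg
            specimen_ids.append(f"{label}_s{j + 1:02d}")
            species_ids.append(label)
            row += 1
    return coords, specimen_ids, species_ids


def _random_rigid_motion(cfg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d = cfg.shape[1]
    A = rng.standard_normal((d, d))
    q, r = np.linalg.qr(A)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    scale = np.exp(rng.normal(0.0, 0.2))
    shift = rng.normal(0.0, 1.0, d)
    return scale * cfg @ q + shift
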