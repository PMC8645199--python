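"""Divergence comparison between two trait complexes (approach 1).

Pairwise Procrustes distances among species mean shapes quantify
divergence within each jaw; a partial Mantel test — correlating the two
divergence matrices while controlling for phylogenetic (patristic)
distance — asks whether divergence in one jaw predicts divergence in the
other. Distances indirectly account for the directionality of change:
species pairs that diverged by the same amount but in opposite
directions do not support a correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import DistanceMatrix
from .shapes import SpeciesMeanShape, procrustes_distance

__all__ = [
    "MantelResult",
    "pairwise_shape_distances",
    "partial_mantel",
    "read_distance_csv",
    "write_distance_csv",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int


def pairwise_shape_distances(
    means: list[SpeciesMeanShape], scale: bool = True
) -> DistanceMatrix:
    """Symmetric matrix of Procrustes distances over all species pairs."""
    if len(means) < 2:
        raise ValueError("need at least 2 species means")
    labels = [m.species_id for m in means]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species ids in mean shapes")
    n = len(means)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = procrustes_distance(
                means[i], means[j], scale=scale
            )
    return DistanceMatrix(tuple(labels), d)


def _partial_r(v1: np.ndarray, v2: np.ndarray, v3: np.ndarray | None) -> float:
    r12 = np.corrcoef(v1, v2)[0, 1]
    if v3 is None:
        return float(r12)
    r13 = np.corrcoef(v1, v3)[0, 1]
    r23 = np.corrcoef(v2, v3)[0, 1]
    return float((r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2)))


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    control: DistanceMatrix | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """Partial Mantel test of d1 vs d2 given a control matrix.

    The statistic is the first-order partial Pearson correlation of the
    lower-triangle entries, ``(r12 - r13 r23) / sqrt((1-r13²)(1-r23²))``.
    The null distribution is built by jointly permuting rows and columns
    of ``d1``; the p-value is one-tailed for positive association with
    the add-one rule, so it is never exactly zero. A control matrix with
    zero variance (or ``control=None``) degrades to the simple Mantel
    test. With ``exhaustive=True`` all n! label permutations are
    enumerated instead of sampling (small n only) and the p-value is the
    exact fraction of permutations with a statistic at least the
    observed one (the identity permutation keeps it positive).
    """
    if not exhaustive and n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if d2.labels != d1.labels:
        d2 = d2.reorder(d1.labels)
    v1 = d1.condensed()
    v2 = d2.condensed()
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("constant distance matrix; Mantel statistic undefined")
    v3 = None
    if control is not None:
        if control.labels != d1.labels:
            control = control.reorder(d1.labels)
        v3 = control.condensed()
        if v3.std() == 0:
            v3 = None  # constant control carries no information
    r_obs = _partial_r(v1, v2, v3)
    n = d1.n
    tri = np.tril_indices(n, k=-1)
    m1 = d1.values
    n_ge = 0
    if exhaustive:
        from itertools import permutations as _perms
        from math import factorial

        total = factorial(n)
        if total > 50_000:
            raise ValueError("exhaustive enumeration only feasible for tiny n")
        for perm in _perms(range(n)):
            v1p = m1[np.ix_(perm, perm)][tri]
            if _partial_r(v1p, v2, v3) >= r_obs - 1e-12:
                n_ge += 1
        return MantelResult(r=r_obs, p=n_ge / total,
                            n_permutations=total, seed=seed)
    rng = np.random.default_rng(seed)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        v1p = m1[np.ix_(perm, perm)][tri]
        if _partial_r(v1p, v2, v3) >= r_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations, seed=seed)


def read_distance_csv(source) -> DistanceMatrix:
    """Labelled square CSV (labels in the first column and header)."""
    df = pd.read_csv(source, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance CSV row and column labels differ")
    return DistanceMatrix(tuple(str(l) for l in df.index), df.to_numpy(float))


def write_distance_csv(d: DistanceMatrix) -> str:
    return pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv()
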