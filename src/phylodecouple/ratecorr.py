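"""Branch-rate correlations between two jaws, overall and through time.

Each branch of the ultrametric tree occupies an age interval
``(parent age, child age]`` in My before present. Time windows of fixed
width (default 0.15 My) are laid on a grid anchored at the present;
because very few lineages exist near the root, all branches older than a
merge age (default 8 My) fall into one merged first window. Within each
window, Pearson's r is computed over the rate pairs of the branches
whose age interval overlaps the window; windows with few branches are
flagged rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .evocorr import CorrelationResult
from .phylo import Phylogeny, node_ages
from .ratemodel import BranchRates

__all__ = [
    "TimeWindowCorr",
    "branch_epochs",
    "make_windows",
    "window_rate_correlation",
    "overall_rate_correlation",
]


@dataclass(frozen=True)
class TimeWindowCorr:
    start: float      # older bound (My before present)
    end: float        # younger bound
    branch_ids: tuple[int, ...]
    n_branches: int
    r: float | None   # None when fewer than 3 branches
    p: float | None
    low_n: bool


def branch_epochs(tree: Phylogeny) -> dict[int, tuple[float, float]]:
    """Per-branch (older age, younger age) interval, keyed by child node."""
    ages = node_ages(tree)
    return {
        v: (float(ages[tree.parent[v]]), float(ages[v]))
        for v in range(tree.n_nodes)
        if v != tree.root
    }


def make_windows(
    root_age: float, width: float = 0.15, merge_before: float = 8.0
) -> list[tuple[float, float]]:
    """Ordered (oldest -> youngest) half-open age windows ``(start, end]``.

    The grid is anchored at the present: windows ``(k·w, (k-1)·w]`` for
    ``k = ceil(merge_before/width) .. 1``, preceded by a single merged
    window ``(root_age, merge_before]`` when the merge age is inside the
    tree's depth.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    windows: list[tuple[float, float]] = []
    if merge_before < root_age:
        windows.append((root_age, merge_before))
        grid_top = merge_before
    else:
        grid_top = root_age
    n_grid = int(np.ceil(grid_top / width - 1e-9))
    for k in range(n_grid, 0, -1):
        start = min(k * width, grid_top)
        end = (k - 1) * width
        if start > end:
            windows.append((start, end))
    return windows


def window_rate_correlation(
    rates_a: BranchRates | dict[int, float],
    rates_b: BranchRates | dict[int, float],
    tree: Phylogeny,
    windows: list[tuple[float, float]] | None = None,
    min_branches: int = 7,
) -> list[TimeWindowCorr]:
    """Pearson r of the two jaws' branch rates inside each time window.

    A branch belongs to every window its half-open age interval
    ``(older, younger]`` overlaps. Windows with fewer than 3 branches
    have undefined correlation (reported as missing); windows below
    ``min_branches`` are flagged ``low_n``.
    """
    ra = rates_a.as_dict() if isinstance(rates_a, BranchRates) else dict(rates_a)
    rb = rates_b.as_dict() if isinstance(rates_b, BranchRates) else dict(rates_b)
    epochs = branch_epochs(tree)
    missing = [v for v in epochs if v not in ra or v not in rb]
    if missing:
        raise ValueError(f"rate tables missing branches: {sorted(missing)[:5]}")
    if windows is None:
        windows = make_windows(float(node_ages(tree).max()))
    out = []
    for start, end in windows:
        ids = tuple(
            v for v, (older, younger) in epochs.items()
            # half-open overlap of (older, younger] with (start, end]
            if older > end and younger < start
        )
        n = len(ids)
        if n >= 3:
            xa = np.array([ra[v] for v in ids])
            xb = np.array([rb[v] for v in ids])
            if xa.std() == 0 or xb.std() == 0:
                r, p = None, None
            else:
                rr, pp = stats.pearsonr(xa, xb)
                r, p = float(rr), float(pp)
        else:
            r, p = None, None
        out.append(
            TimeWindowCorr(
                start=float(start), end=float(end), branch_ids=ids,
                n_branches=n, r=r, p=p, low_n=n < min_branches,
            )
        )
    return out


def overall_rate_correlation(
    rates_a: BranchRates | dict[int, float],
    rates_b: BranchRates | dict[int, float],
    exclude: set[int] | None = None,
) -> CorrelationResult:
    """Ordinary Pearson correlation over all (non-excluded) branches."""
    ra = rates_a.as_dict() if isinstance(rates_a, BranchRates) else dict(rates_a)
    rb = rates_b.as_dict() if isinstance(rates_b, BranchRates) else dict(rates_b)
    if set(ra) != set(rb):
        raise ValueError("rate tables cover different branch sets")
    ids = sorted(set(ra) - (exclude or set()))
    if len(ids) < 3:
        raise ValueError("need at least 3 branches for a correlation")
    xa = np.array([ra[v] for v in ids])
    xb = np.array([rb[v] for v in ids])
    r, p = stats.pearsonr(xa, xb)
    return CorrelationResult(r=float(r), p=float(p), df=len(ids) - 2)
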