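"""Multivariate variable-rates Brownian-motion model (approach 3a).

Traits (typically the first three PC axes of one jaw) evolve by Brownian
motion on the time tree, but branch lengths are multiplied by latent
relative-rate scalars shared across traits. A reversible-jump
Metropolis-Hastings sampler explores the number, placement, scope
(single branch or whole clade) and magnitude of rate shifts together
with each trait's ancestral state ``alpha`` and base rate ``sigma2``.
The per-branch relative rate is the product of all scalars whose scope
covers the branch (1 when no shift applies).

The likelihood is evaluated with an O(n) pruning decomposition of the
multivariate-normal density on the rescaled tree: each independent
contrast contributes a univariate normal term and the root adds a final
term for the deviation of the phylogenetically weighted mean from
``alpha``. Traits are modelled as independent given the tree and the
shared scalars (PC axes are orthogonal). The chain, all proposals and
the retained sample are deterministic for a given config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .phylo import Phylogeny, PhylogenyError

__all__ = [
    "RateModelConfig",
    "PosteriorSample",
    "BranchRates",
    "log_likelihood",
    "run_mcmc",
    "ess",
    "split_posterior",
    "summarize_rates",
]

SCOPE_BRANCH = 0
SCOPE_CLADE = 1
_SCALAR_LOG_SD = 1.5          # log-normal shift-magnitude prior spread
_SCALAR_LOG_BOUND = np.log(1e3)  # truncation: scalars in (1e-3, 1e3)
_SHIFT_RATE = 1.0             # Poisson mean of the shift-count prior


@dataclass(frozen=True)
class RateModelConfig:
    """Priors, chain length and move settings for one MCMC run.

    Defaults mirror a desk-scale run: 2e6 iterations thinned every 200
    after a 2e5 burnin; alpha uniform on (-1, 1); per-trait sigma2
    uniform on (0, upper) with dataset-specific uppers.
    """

    alpha_bounds: tuple[float, float] = (-1.0, 1.0)
    sigma2_upper: tuple[float, ...] = (1e-4, 1e-4, 1e-4)
    n_iterations: int = 2_000_000
    burnin: int = 200_000
    thin: int = 200
    seed: int = 0
    allow_clade_scalars: bool = True
    max_shifts: int = 50
    likelihood_on: bool = True  # off = prior-only run (sampler diagnostics)

    def __post_init__(self) -> None:
        lo, hi = self.alpha_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("alpha bounds must be finite with lo < hi")
        if any(u <= 0 or not np.isfinite(u) for u in self.sigma2_upper):
            raise ValueError("sigma2 uppers must be finite and > 0")
        if self.burnin >= self.n_iterations:
            raise ValueError("burnin must be < n_iterations")
        if (self.n_iterations - self.burnin) % self.thin != 0:
            raise ValueError("thin must divide (n_iterations - burnin) evenly")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha_bounds": list(self.alpha_bounds),
                "sigma2_upper": list(self.sigma2_upper),
                "n_iterations": self.n_iterations,
                "burnin": self.burnin,
                "thin": self.thin,
                "seed": self.seed,
                "allow_clade_scalars": self.allow_clade_scalars,
                "max_shifts": self.max_shifts,
                "likelihood_on": self.likelihood_on,
            },
            indent=2,
        )


@dataclass
class PosteriorSample:
    """Retained MCMC draws.

    ``relative_rates`` holds, per draw, the realized per-branch relative
    rate (branch indexed by its child node; the root entry is unused and
    kept at 1).
    """

    tree: Phylogeny
    config: RateModelConfig
    alphas: np.ndarray          # (S, K)
    sigma2s: np.ndarray         # (S, K)
    log_likelihoods: np.ndarray  # (S,)
    relative_rates: np.ndarray  # (S, n_nodes)
    shift_branches: np.ndarray  # (S, max_shifts) int, -1 padded
    shift_scopes: np.ndarray    # (S, max_shifts) int
    shift_scalars: np.ndarray   # (S, max_shifts) float
    shift_counts: np.ndarray    # (S,)
    acceptance_rate: float

    @property
    def size(self) -> int:
        return self.alphas.shape[0]

    def subset(self, mask: np.ndarray) -> "PosteriorSample":
        return PosteriorSample(
            self.tree, self.config,
            self.alphas[mask], self.sigma2s[mask],
            self.log_likelihoods[mask], self.relative_rates[mask],
            self.shift_branches[mask], self.shift_scopes[mask],
            self.shift_scalars[mask], self.shift_counts[mask],
            self.acceptance_rate,
        )

    def parameter_ess(self) -> dict[str, float]:
        """ESS per alpha/sigma2/logL series (flagged against 200 by callers)."""
        out = {}
        for k in range(self.alphas.shape[1]):
            out[f"alpha_{k + 1}"] = ess(self.alphas[:, k])
            out[f"sigma2_{k + 1}"] = ess(self.sigma2s[:, k])
        out["log_likelihood"] = ess(self.log_likelihoods)
        return out


@dataclass(frozen=True)
class BranchRates:
    """Per-branch posterior-mean relative rate (child-node indexed)."""

    tree: Phylogeny
    relative: np.ndarray                 # (n_nodes,), root entry 1
    absolute: np.ndarray | None = None   # (n_nodes, K) sigma2-scaled

    def as_dict(self) -> dict[int, float]:
        return {
            v: float(self.relative[v])
            for v in range(self.tree.n_nodes)
            if v != self.tree.root
        }


# -- tree flattening for the jitted kernels --------------------------------


def _flat_tree(tree: Phylogeny):
    if not tree.is_bifurcating():
        raise PhylogenyError("variable-rates model requires a bifurcating tree")
    internal, left, right = [], [], []
    for v in tree.postorder:
        kids = tree.children[v]
        if kids:
            internal.append(v)
            left.append(kids[0])
            right.append(kids[1])
    desc = np.zeros((tree.n_nodes, tree.n_nodes), dtype=np.uint8)
    for v in tree.postorder:
        desc[v, v] = 1
        for c in tree.children[v]:
            desc[v] |= desc[c]
    return (
        np.array(internal, dtype=np.int64),
        np.array(left, dtype=np.int64),
        np.array(right, dtype=np.int64),
        desc,
    )


@njit(cache=True)
def _pruning_loglik(traits, internal, left, right, root, lengths,
                    alphas, sigma2s):  # pragma: no cover - jitted
    n_tips, K = traits.shape
    n_nodes = lengths.shape[0]
    x = np.zeros((n_nodes, K))
    x[:n_tips] = traits
    v = lengths.copy()
    ll = 0.0
    log2pi = np.log(2.0 * np.pi)
    for idx in range(internal.shape[0]):
        nd = internal[idx]
        a = left[idx]
        b = right[idx]
        va = v[a]
        vb = v[b]
        Vc = va + vb
        for k in range(K):
            c = x[a, k] - x[b, k]
            s2 = sigma2s[k] * Vc
            ll += -0.5 * (log2pi + np.log(s2)) - c * c / (2.0 * s2)
        w = 1.0 / va + 1.0 / vb
        for k in range(K):
            x[nd, k] = (x[a, k] / va + x[b, k] / vb) / w
        v[nd] += va * vb / Vc
    vr = v[root]
    for k in range(K):
        s2 = sigma2s[k] * vr
        d = x[root, k] - alphas[k]
        ll += -0.5 * (log2pi + np.log(s2)) - d * d / (2.0 * s2)
    return ll


@njit(cache=True)
def _relative_rates(n_nodes, shift_branch, shift_scope, shift_scalar, k_shifts,
                    desc):  # pragma: no cover - jitted
    rates = np.ones(n_nodes)
    for s in range(k_shifts):
        b = shift_branch[s]
        if shift_scope[s] == 0:
            rates[b] *= shift_scalar[s]
        else:
            for vtx in range(n_nodes):
                if desc[b, vtx] == 1:
                    rates[vtx] *= shift_scalar[s]
    return rates


@njit(cache=True)
def _run_chain(traits, internal, left, right, root, base_lengths, desc,
               alpha_lo, alpha_hi, sigma_hi,
               n_iterations, burnin, thin, seed, allow_clade, max_shifts,
               likelihood_on):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_nodes = base_lengths.shape[0]
    n_branches = n_nodes - 1
    K = traits.shape[1]
    n_scopes = 2 if allow_clade == 1 else 1
    total_slots = n_branches * n_scopes

    alphas = np.empty(K)
    sigma2s = np.empty(K)
    for k in range(K):
        alphas[k] = 0.5 * (alpha_lo + alpha_hi)
        sigma2s[k] = 0.5 * sigma_hi[k]
    sb = np.full(max_shifts, -1, dtype=np.int64)
    sc = np.zeros(max_shifts, dtype=np.int64)
    ss = np.ones(max_shifts)
    k_shifts = 0

    alpha_w = 0.1 * (alpha_hi - alpha_lo)
    tau = 0.4  # scalar random-walk log sd

    rates = np.ones(n_nodes)
    lengths = base_lengths * rates
    if likelihood_on == 1:
        cur_ll = _pruning_loglik(traits, internal, left, right, root, lengths,
                                 alphas, sigma2s)
    else:
        cur_ll = 0.0

    S = (n_iterations - burnin) // thin
    out_alpha = np.empty((S, K))
    out_sigma = np.empty((S, K))
    out_ll = np.empty(S)
    out_rates = np.empty((S, n_nodes))
    out_sb = np.full((S, max_shifts), -1, dtype=np.int64)
    out_sc = np.zeros((S, max_shifts), dtype=np.int64)
    out_ss = np.ones((S, max_shifts))
    out_k = np.zeros(S, dtype=np.int64)
    n_accept = 0
    s_out = 0

    for it in range(1, n_iterations + 1):
        u = np.random.random()
        accept = False
        if u < 0.25:
            # ancestral state slide with reflection
            k = np.random.randint(0, K)
            prop = alphas[k] + (np.random.random() * 2.0 - 1.0) * alpha_w
            for _ in range(100):
                if prop < alpha_lo:
                    prop = 2.0 * alpha_lo - prop
                elif prop > alpha_hi:
                    prop = 2.0 * alpha_hi - prop
                else:
                    break
            old = alphas[k]
            alphas[k] = prop
            if likelihood_on == 1:
                new_ll = _pruning_loglik(traits, internal, left, right, root,
                                         lengths, alphas, sigma2s)
            else:
                new_ll = 0.0
            if np.log(np.random.random()) < new_ll - cur_ll:
                cur_ll = new_ll
                accept = True
            else:
                alphas[k] = old
        elif u < 0.5:
            # base-rate slide with reflection at (0, hi)
            k = np.random.randint(0, K)
            w = 0.1 * sigma_hi[k]
            prop = sigma2s[k] + (np.random.random() * 2.0 - 1.0) * w
            for _ in range(100):
                if prop < 0.0:
                    prop = -prop
                elif prop > sigma_hi[k]:
                    prop = 2.0 * sigma_hi[k] - prop
                else:
                    break
            if prop > 0.0:
                old = sigma2s[k]
                sigma2s[k] = prop
                if likelihood_on == 1:
                    new_ll = _pruning_loglik(traits, internal, left, right,
                                             root, lengths, alphas, sigma2s)
                else:
                    new_ll = 0.0
                if np.log(np.random.random()) < new_ll - cur_ll:
                    cur_ll = new_ll
                    accept = True
                else:
                    sigma2s[k] = old
        elif u < 0.65:
            # multiplicative walk on an existing scalar
            if k_shifts > 0:
                j = np.random.randint(0, k_shifts)
                lold = np.log(ss[j])
                lnew = lold + np.random.normal(0.0, tau)
                if abs(lnew) < _SCALAR_LOG_BOUND:
                    old_s = ss[j]
                    ss[j] = np.exp(lnew)
                    new_rates = _relative_rates(n_nodes, sb, sc, ss, k_shifts,
                                                desc)
                    new_lengths = base_lengths * new_rates
                    if likelihood_on == 1:
                        new_ll = _pruning_loglik(traits, internal, left, right,
                                                 root, new_lengths, alphas,
                                                 sigma2s)
                    else:
                        new_ll = 0.0
                    # lognormal prior x Hastings for the multiplicative walk
                    log_ratio = (new_ll - cur_ll) - (
                        lnew * lnew - lold * lold
                    ) / (2.0 * _SCALAR_LOG_SD * _SCALAR_LOG_SD)
                    if np.log(np.random.random()) < log_ratio:
                        cur_ll = new_ll
                        rates = new_rates
                        lengths = new_lengths
                        accept = True
                    else:
                        ss[j] = old_s
        elif u < 0.825:
            # birth of a shift on a free (branch, scope) slot
            if k_shifts < max_shifts and k_shifts < total_slots:
                for _ in range(1000):
                    cand = np.random.randint(0, n_branches)
                    if cand >= root:
                        cand += 1  # skip the root (no branch above it)
                    scope = np.random.randint(0, n_scopes)
                    occupied = False
                    for j in range(k_shifts):
                        if sb[j] == cand and sc[j] == scope:
                            occupied = True
                            break
                    if not occupied:
                        break
                if not occupied:
                    e = np.random.normal(0.0, _SCALAR_LOG_SD)
                    while abs(e) >= _SCALAR_LOG_BOUND:
                        e = np.random.normal(0.0, _SCALAR_LOG_SD)
                    sb[k_shifts] = cand
                    sc[k_shifts] = scope
                    ss[k_shifts] = np.exp(e)
                    new_rates = _relative_rates(n_nodes, sb, sc, ss,
                                                k_shifts + 1, desc)
                    new_lengths = base_lengths * new_rates
                    if likelihood_on == 1:
                        new_ll = _pruning_loglik(traits, internal, left, right,
                                                 root, new_lengths, alphas,
                                                 sigma2s)
                    else:
                        new_ll = 0.0
                    # uniform-over-slot-sets prior: the slot-choice terms
                    # cancel against the proposal, leaving the count-prior
                    # ratio only
                    log_ratio = (new_ll - cur_ll) + np.log(
                        _SHIFT_RATE / (k_shifts + 1.0)
                    )
                    if np.log(np.random.random()) < log_ratio:
                        cur_ll = new_ll
                        rates = new_rates
                        lengths = new_lengths
                        k_shifts += 1
                        accept = True
                    else:
                        sb[k_shifts] = -1
                        sc[k_shifts] = 0
                        ss[k_shifts] = 1.0
        else:
            # death of an existing shift
            if k_shifts > 0:
                j = np.random.randint(0, k_shifts)
                db, dc, dsv = sb[j], sc[j], ss[j]
                sb[j] = sb[k_shifts - 1]
                sc[j] = sc[k_shifts - 1]
                ss[j] = ss[k_shifts - 1]
                sb[k_shifts - 1] = -1
                sc[k_shifts - 1] = 0
                ss[k_shifts - 1] = 1.0
                new_rates = _relative_rates(n_nodes, sb, sc, ss, k_shifts - 1,
                                            desc)
                new_lengths = base_lengths * new_rates
                if likelihood_on == 1:
                    new_ll = _pruning_loglik(traits, internal, left, right,
                                             root, new_lengths, alphas,
                                             sigma2s)
                else:
                    new_ll = 0.0
                log_ratio = (new_ll - cur_ll) + np.log(
                    k_shifts / _SHIFT_RATE
                )
                if np.log(np.random.random()) < log_ratio:
                    cur_ll = new_ll
                    rates = new_rates
                    lengths = new_lengths
                    k_shifts -= 1
                    accept = True
                else:
                    sb[k_shifts - 1] = sb[j]
                    sc[k_shifts - 1] = sc[j]
                    ss[k_shifts - 1] = ss[j]
                    sb[j] = db
                    sc[j] = dc
                    ss[j] = dsv
        if accept:
            n_accept += 1
        if it > burnin and (it - burnin) % thin == 0:
            out_alpha[s_out] = alphas
            out_sigma[s_out] = sigma2s
            out_ll[s_out] = cur_ll
            out_rates[s_out] = rates
            out_sb[s_out] = sb
            out_sc[s_out] = sc
            out_ss[s_out] = ss
            out_k[s_out] = k_shifts
            s_out += 1
    return (out_alpha, out_sigma, out_ll, out_rates, out_sb, out_sc, out_ss,
            out_k, n_accept / n_iterations)


# -- public operations -----------------------------------------------------


def log_likelihood(
    traits: np.ndarray,
    tree: Phylogeny,
    alphas: np.ndarray,
    sigma2s: np.ndarray,
    shift_set: list[tuple[int, str, float]] | None = None,
) -> float:
    """Log-likelihood of the variable-rates model.

    ``traits`` is (n_tips, K) in ``tree.tip_labels`` order; ``shift_set``
    entries are ``(branch_child_node, scope, scalar)`` with scope
    ``"branch"`` or ``"clade"``. The tree is rescaled by the product of
    applicable scalars per branch and each trait contributes an
    independent Brownian-motion density.
    """
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    if traits.shape[0] != tree.n_tips:
        raise ValueError("traits must have one row per tip")
    sigma2s = np.asarray(sigma2s, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    if (sigma2s <= 0).any():
        raise ValueError("sigma2s must be > 0")
    internal, left, right, desc = _flat_tree(tree)
    rates = np.ones(tree.n_nodes)
    for branch, scope, scalar in shift_set or []:
        if scalar <= 0:
            raise ValueError("shift scalars must be > 0")
        if scope == "branch":
            rates[branch] *= scalar
        elif scope == "clade":
            rates[desc[branch].astype(bool)] *= scalar
        else:
            raise ValueError(f"unknown scope {scope!r}")
    lengths = tree.branch_lengths * rates
    return float(
        _pruning_loglik(
            traits, internal, left, right, tree.root, lengths, alphas, sigma2s
        )
    )


def run_mcmc(
    traits: np.ndarray, tree: Phylogeny, config: RateModelConfig
) -> PosteriorSample:
    """Reversible-jump MCMC over rate shifts, alphas and sigma2s."""
    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    if traits.shape[0] != tree.n_tips:
        raise ValueError("traits must have one row per tip")
    K = traits.shape[1]
    sigma_hi = np.asarray(config.sigma2_upper, dtype=float)
    if sigma_hi.size == 1 and K > 1:
        sigma_hi = np.repeat(sigma_hi, K)
    if sigma_hi.size != K:
        raise ValueError("one sigma2 upper bound per trait required")
    internal, left, right, desc = _flat_tree(tree)
    res = _run_chain(
        traits, internal, left, right, tree.root,
        tree.branch_lengths.astype(float), desc,
        float(config.alpha_bounds[0]), float(config.alpha_bounds[1]),
        sigma_hi,
        config.n_iterations, config.burnin, config.thin,
        config.seed % (2**31), 1 if config.allow_clade_scalars else 0,
        config.max_shifts, 1 if config.likelihood_on else 0,
    )
    (alpha, sigma, ll, rates, sb, sc, ss, kk, acc) = res
    return PosteriorSample(
        tree=tree, config=config, alphas=alpha, sigma2s=sigma,
        log_likelihoods=ll, relative_rates=rates, shift_branches=sb,
        shift_scopes=sc, shift_scalars=ss, shift_counts=kk,
        acceptance_rate=float(acc),
    )


def ess(series: np.ndarray) -> float:
    """Effective sample size with initial-positive-sequence truncation.

    ``N / (1 + 2 sum rho_t)`` where autocorrelations are accumulated
    until the first consecutive pair sums non-positive; capped at N.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("series too short for an ESS estimate (need >= 10)")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no defined ESS")
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    tau = max(1.0 + 2.0 * s, 1.0 / n)
    return float(min(n / tau, n))


def split_posterior(
    sample: PosteriorSample, thresholds: np.ndarray | list[float]
) -> tuple[PosteriorSample, PosteriorSample, dict[str, float]]:
    """Split a (bimodal) posterior at per-trait sigma2 cutoffs.

    A draw belongs to optimum 1 when every trait's sigma2 is below its
    threshold and to optimum 2 when every one is at or above; draws
    satisfying neither are dropped. Posterior probabilities are the
    optima's fractions of the full sample.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size != sample.sigma2s.shape[1]:
        raise ValueError("one threshold per trait required")
    low = (sample.sigma2s < thr).all(axis=1)
    high = (sample.sigma2s >= thr).all(axis=1)
    mixed = ~(low | high)
    info = {
        "pp_optimum1": float(low.mean()),
        "pp_optimum2": float(high.mean()),
        "dropped_fraction": float(mixed.mean()),
        "n_dropped": int(mixed.sum()),
    }
    return sample.subset(low), sample.subset(high), info


def summarize_rates(
    sample: PosteriorSample, absolute: bool = False
) -> BranchRates:
    """Posterior-mean relative rate per branch (optionally sigma2-scaled)."""
    if sample.size == 0:
        raise ValueError("empty posterior sample")
    rel = sample.relative_rates.mean(axis=0)
    rel[sample.tree.root] = 1.0
    abs_rates = None
    if absolute:
        # per trait: mean over draws of sigma2_k x relative rate
        abs_rates = np.einsum(
            "sk,sn->nk", sample.sigma2s, sample.relative_rates
        ) / sample.size
    return BranchRates(sample.tree, rel, abs_rates)
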