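"""Variable-rates likelihood, reversible-jump sampler, and diagnostics."""

import copy

import numpy as np
import pytest
from scipy.stats import chisquare, multivariate_normal, poisson

from phylodecouple import ratemodel as rm
from phylodecouple.phylo import phylo_covariance, read_newick
from phylodecouple.synthetic_data import (
    _clade_nodes,
    make_scenario,
    simulate_jaw_traits,
    simulate_tree,
)


def dense_loglik(tree, traits, alphas, sigma2s, shift_set):
    """Independent oracle: rescale a copied tree branch-by-branch, build
    the dense BM covariance, and sum exact MVN log-densities."""
    rates = np.ones(tree.n_nodes)
    for b, scope, s in shift_set:
        if scope == "branch":
            rates[b] *= s
        else:
            for v in _clade_nodes(tree, b):
                rates[v] *= s
    t2 = copy.deepcopy(tree)
    t2.branch_lengths = tree.branch_lengths * rates
    C = phylo_covariance(t2)
    return sum(
        multivariate_normal.logpdf(
            traits[:, k], mean=np.full(tree.n_tips, alphas[k]),
            cov=sigma2s[k] * C,
        )
        for k in range(traits.shape[1])
    )


class TestLogLikelihood:
    def test_bivariate_standard_normal_closed_form(self, cherry):
        ll = rm.log_likelihood(
            np.zeros((2, 1)), cherry, alphas=[0.0], sigma2s=[1.0]
        )
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_empty_shift_set_equals_plain_bm(self, small_tree):
        rng = np.random.default_rng(0)
        traits = rng.normal(0, 0.05, (small_tree.n_tips, 2))
        a = rm.log_likelihood(traits, small_tree, [0.0, 0.0], [1e-4, 1e-4])
        b = rm.log_likelihood(
            traits, small_tree, [0.0, 0.0], [1e-4, 1e-4], shift_set=[]
        )
        assert a == b

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(int(rng.integers(4, 13)), 10.0, seed=seed)
        K = int(rng.integers(1, 4))
        traits = rng.normal(0, 0.1, (tree.n_tips, K))
        alphas = rng.uniform(-0.5, 0.5, K)
        sigma2s = rng.uniform(1e-4, 1e-2, K)
        shifts = []
        for _ in range(int(rng.integers(0, 3))):
            b = int(rng.integers(0, tree.n_nodes))
            if b == tree.root:
                b = (b + 1) % tree.n_nodes
            shifts.append(
                (b, rng.choice(["branch", "clade"]),
                 float(np.exp(rng.normal(0, 1))))
            )
        got = rm.log_likelihood(traits, tree, alphas, sigma2s, shifts)
        want = dense_loglik(tree, traits, alphas, sigma2s, shifts)
        assert got == pytest.approx(want, abs=1e-8)

    def test_nonpositive_sigma_rejected(self, cherry):
        with pytest.raises(ValueError, match="sigma2"):
            rm.log_likelihood(np.zeros((2, 1)), cherry, [0.0], [0.0])


class TestConfig:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError, match="burnin"):
            rm.RateModelConfig(n_iterations=100, burnin=100, thin=1)

    def test_thin_must_divide(self):
        with pytest.raises(ValueError, match="thin"):
            rm.RateModelConfig(n_iterations=1000, burnin=100, thin=7)


class TestSampler:
    def test_prior_only_shift_count_matches_prior(self, small_tree):
        """With the likelihood disabled the chain must sample the
        truncated Poisson(1) shift-count prior (chi-square GOF)."""
        cfg = rm.RateModelConfig(
            sigma2_upper=(1e-3,), n_iterations=1_000_000, burnin=100_000,
            thin=100, seed=13, likelihood_on=False,
        )
        s = rm.run_mcmc(np.zeros((small_tree.n_tips, 1)), small_tree, cfg)
        kmax = 7
        obs = np.bincount(np.minimum(s.shift_counts, kmax), minlength=kmax + 1)
        exp = poisson.pmf(np.arange(kmax + 1), 1.0)
        exp[-1] = 1 - exp[:-1].sum()
        res = chisquare(obs, exp * obs.sum())
        assert res.pvalue > 0.01

    def test_no_false_shifts_on_bm_data(self, small_tree):
        scn = make_scenario("decoupled", n_tips=50, seed=21)
        traits, _ = simulate_jaw_traits(small_tree, scn)
        cfg = rm.RateModelConfig(
            sigma2_upper=(1e-3,) * 3, n_iterations=1_000_000,
            burnin=100_000, thin=100, seed=1,
        )
        s = rm.run_mcmc(traits, small_tree, cfg)
        mean_rates = np.delete(s.relative_rates.mean(axis=0), small_tree.root)
        frac = np.mean((mean_rates >= 0.5) & (mean_rates <= 2.0))
        assert frac >= 0.9

    def test_planted_clade_shift_recovered(self):
        hits = 0
        for seed in range(3):
            tree = simulate_tree(50, 10.0, seed=300 + seed)
            clade = next(
                v for v in range(tree.n_tips, tree.n_nodes)
                if 8 <= sum(u < tree.n_tips for u in _clade_nodes(tree, v)) <= 14
            )
            tips = frozenset(
                tree.tip_labels[u] for u in _clade_nodes(tree, clade)
                if u < tree.n_tips
            )
            scn = make_scenario(
                "shifted_clade", n_tips=50, seed=seed,
                planted_shifts=((tips, 10.0),),
            )
            traits, _ = simulate_jaw_traits(tree, scn)
            cfg = rm.RateModelConfig(
                sigma2_upper=(1e-3,) * 3, n_iterations=1_000_000,
                burnin=100_000, thin=100, seed=seed,
            )
            mr = rm.run_mcmc(traits, tree, cfg).relative_rates.mean(axis=0)
            inside = [v for v in _clade_nodes(tree, clade) if v != clade]
            outside = [
                v for v in range(tree.n_nodes)
                if v != tree.root and v not in inside
            ]
            hits += mr[inside].mean() > mr[outside].mean()
        assert hits == 3

    def test_chain_reproducible_byte_for_byte(self, small_tree):
        scn = make_scenario("decoupled", n_tips=50, seed=5)
        traits, _ = simulate_jaw_traits(small_tree, scn)
        cfg = rm.RateModelConfig(
            sigma2_upper=(1e-3,) * 3, n_iterations=100_000, burnin=10_000,
            thin=100, seed=77,
        )
        a = rm.run_mcmc(traits, small_tree, cfg)
        b = rm.run_mcmc(traits, small_tree, cfg)
        assert np.array_equal(a.alphas, b.alphas)
        assert np.array_equal(a.sigma2s, b.sigma2s)
        assert np.array_equal(a.relative_rates, b.relative_rates)
        assert np.array_equal(a.shift_scalars, b.shift_scalars)

    def test_posterior_covers_truth(self):
        """Central 90% posterior intervals of alpha and sigma2 cover the
        generating values in most seeded replicates."""
        covered_alpha = covered_sigma = 0
        n_seeds = 10
        for seed in range(n_seeds):
            tree = simulate_tree(50, 10.0, seed=500 + seed)
            rng = np.random.default_rng(seed)
            x = np.empty(tree.n_nodes)
            x[tree.root] = 0.2
            for v in tree.postorder[::-1]:
                if v != tree.root:
                    x[v] = x[tree.parent[v]] + rng.normal(
                        0, np.sqrt(5e-5 * tree.branch_lengths[v])
                    )
            traits = x[: tree.n_tips, None]
            cfg = rm.RateModelConfig(
                sigma2_upper=(1e-4,), n_iterations=300_000, burnin=30_000,
                thin=100, seed=seed,
            )
            s = rm.run_mcmc(traits, tree, cfg)
            qa = np.quantile(s.alphas[:, 0], [0.05, 0.95])
            qs = np.quantile(s.sigma2s[:, 0], [0.05, 0.95])
            covered_alpha += qa[0] <= 0.2 <= qa[1]
            covered_sigma += qs[0] <= 5e-5 <= qs[1]
        assert covered_alpha >= 7
        assert covered_sigma >= 7


class TestESS:
    def test_iid_series(self):
        x = np.random.default_rng(0).normal(0, 1, 10_000)
        assert 8_500 <= rm.ess(x) <= 11_500

    def test_ar1_closed_form(self):
        rng = np.random.default_rng(1)
        n, rho = 50_000, 0.5
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(0, np.sqrt(1 - rho**2), n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        ratio = rm.ess(x) / n
        assert 0.28 <= ratio <= 0.39

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            rm.ess(np.arange(5.0))

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rm.ess(np.ones(100))


class TestPosteriorSummaries:
    @staticmethod
    def toy_sample(tree, sigma2s, rates_rows, counts=None):
        S = len(rates_rows)
        K = sigma2s.shape[1]
        return rm.PosteriorSample(
            tree=tree,
            config=rm.RateModelConfig(
                sigma2_upper=(1.0,) * K, n_iterations=1000, burnin=0, thin=1
            ),
            alphas=np.zeros((S, K)),
            sigma2s=sigma2s,
            log_likelihoods=np.zeros(S),
            relative_rates=np.asarray(rates_rows, dtype=float),
            shift_branches=np.full((S, 5), -1, dtype=np.int64),
            shift_scopes=np.zeros((S, 5), dtype=np.int64),
            shift_scalars=np.ones((S, 5)),
            shift_counts=np.zeros(S, dtype=np.int64)
            if counts is None else np.asarray(counts),
            acceptance_rate=0.5,
        )

    def test_no_shifts_mean_rate_one(self, cherry):
        s = self.toy_sample(cherry, np.full((4, 1), 0.5), np.ones((4, 3)))
        br = rm.summarize_rates(s)
        assert np.all(br.relative == 1.0)

    def test_mean_of_two_scalars(self, cherry):
        rows = np.ones((2, 3))
        rows[0, 0] = 2.0
        rows[1, 0] = 4.0
        s = self.toy_sample(cherry, np.full((2, 1), 0.5), rows)
        br = rm.summarize_rates(s)
        assert br.relative[0] == pytest.approx(3.0)

    def test_absolute_rates_reconcile_subchains(self, cherry):
        """Low sigma2 with high scalars and high sigma2 with low scalars
        describe the same absolute rates."""
        rows_low = np.full((3, 3), 4.0)
        rows_high = np.full((3, 3), 1.0)
        s_low = self.toy_sample(cherry, np.full((3, 1), 2.5e-4), rows_low)
        s_high = self.toy_sample(cherry, np.full((3, 1), 1e-3), rows_high)
        abs_low = rm.summarize_rates(s_low, absolute=True).absolute
        abs_high = rm.summarize_rates(s_high, absolute=True).absolute
        np.testing.assert_allclose(abs_low, abs_high, rtol=0.05)

    def test_split_posterior_counting(self, cherry):
        sigma = np.concatenate([
            np.full((30, 2), 0.1),          # below both thresholds
            np.full((60, 2), 0.9),          # above both
            np.column_stack([np.full(10, 0.1), np.full(10, 0.9)]),  # mixed
        ])
        s = self.toy_sample(cherry, sigma, np.ones((100, 3)))
        low, high, info = rm.split_posterior(s, [0.5, 0.5])
        assert info["pp_optimum1"] == pytest.approx(0.3)
        assert info["pp_optimum2"] == pytest.approx(0.6)
        assert info["dropped_fraction"] == pytest.approx(0.1)
        assert low.size == 30 and high.size == 60

    def test_split_all_below(self, cherry):
        s = self.toy_sample(cherry, np.full((10, 1), 0.1), np.ones((10, 3)))
        _, _, info = rm.split_posterior(s, [0.5])
        assert info["pp_optimum1"] == 1.0 and info["pp_optimum2"] == 0.0

    def test_empty_sample_rejected(self, cherry):
        s = self.toy_sample(cherry, np.zeros((0, 1)), np.zeros((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            rm.summarize_rates(s)
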