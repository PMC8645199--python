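# phylodecouple

Phylogenetic comparative tests for **evolutionary decoupling** of two
morphological trait complexes.

## The scientific problem

In trophically diverse radiations — the motivating system is the cichlid
species flock of an East African rift lake, where two jaw systems divide
the labour of feeding — a classic hypothesis holds that the pharyngeal
jaw apparatus acted as a key innovation by freeing the oral jaws from
food processing, letting the two jaws follow independent evolutionary
trajectories. Testing that hypothesis requires asking, across the tips
of a time-calibrated phylogeny, whether two landmark-based trait
complexes (here: a 4-landmark 2-D premaxilla retaining its size and
orientation relative to the body, and a mirrored 3-D lower pharyngeal
jaw configuration) evolved in a correlated or a decoupled fashion.

`phylodecouple` implements three complementary approaches as a tested,
reusable pipeline, plus a synthetic-data generator that emulates the
statistical structure of such a radiation so every stage can be
exercised without any empirical download:

1. **Divergence** (`divergence`) — pairwise Procrustes distances among
   species mean shapes for each jaw, compared with a partial Mantel
   test that controls for patristic (phylogenetic) distance. The
   statistic is the first-order partial correlation
   r = (r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²)) over lower-triangle entries,
   with a one-tailed permutation p (rows/columns of the first matrix
   permuted jointly; add-one rule).
2. **Evolutionary correlations** (`evocorr`) — phylogenetically
   independent contrasts (Felsenstein's pruning) of shape PC axes,
   correlated through the origin (r = Σxᵢyᵢ/√(Σxᵢ²Σyᵢ²), df = n−2 for n
   tips i.e. contrasts − 1) and judged against a null band of contrast
   correlations between 1000 independent Brownian-motion trait pairs
   simulated on the same tree; plus a phylogenetic two-block partial
   least squares (pPLS) fit — SVD of the evolutionary cross-covariance
   X₁ᶜᵀC⁻¹X₂ᶜ/(n−1) — measuring integration along the axes of most
   covariance.
3. **Evolutionary rates** (`ratemodel`, `ratecorr`) — a multivariate
   variable-rates Brownian-motion model in which branch lengths are
   multiplied by latent relative-rate scalars (branch- or clade-scoped)
   sampled by reversible-jump MCMC; the per-branch posterior mean rates
   of the two jaws are then correlated overall and within 0.15-My time
   windows along the phylogeny (branches older than 8 My pooled into
   one window).

## Worked example

```python
from phylodecouple import synthetic_data as sd
from phylodecouple.pipeline import generate_synthetic_inputs, run_full_analysis

scenario = sd.make_scenario("coupled", n_tips=40, seed=7,
                            n_specimens_per_species=3)
config = generate_synthetic_inputs(scenario, "example_run")
config.rate_iterations, config.rate_burnin, config.rate_thin = 100_000, 10_000, 100
config.mantel_permutations = config.pls_permutations = 199
config.null_pairs = 200
report = run_full_analysis(config)
print(report["mantel"])
print(report["pic_grid"]["r"][0], report["pic_grid"]["null_max"])
print(report["pls"])
```

This generates a 40-species radiation whose two jaw blocks share a
strong (ρ = 0.9) process-level coupling, runs all three approaches, and
printed on our machine:

```
{'r': 0.7490506238509398, 'p': 0.005, 'n_permutations': 199}
[0.866408053509644, 0.1420889598948115, -0.19188504382452562] 0.4986052013479526
{'r_pls': 0.8733014722709486, 'p': 0.005}
```

Read: divergence matrices of the two jaws are strongly associated after
controlling for phylogeny (partial Mantel r = 0.75, smallest achievable
p at 199 permutations); the leading PC axes of the two jaws show an
evolutionary correlation (r = 0.87) far outside the Brownian-motion
null band (max |r| ≈ 0.50 at 40 tips), while the off-axis correlations
stay inside it; and the pPLS integration axis confirms the coupling
(r = 0.87, p = 0.005). A `decoupled` scenario (ρ = 0) leaves all of
these inside their null expectations. `run_full_analysis` also writes
`report.json`, a human-readable `summary.txt`, distance matrices, and
per-branch rate tables into the configured output directory.

A CLI mirrors the stages (`phylodecouple simulate | analyze |
divergence | evocorr | rates | ratecorr`); see `phylodecouple --help`.

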