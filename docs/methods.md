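# Methods

This note records the models, conventions and design decisions behind
`phylodecouple`, in the spirit of a methods appendix. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tree handling (`phylo`)

Trees are rooted, with branch lengths in millions of years (My)
throughout; no unit conversion is ever applied. Newick parsing and
writing are delegated to dendropy, after which the tree is flattened to
parent-pointer arrays with tips indexed in sorted-label order, making
every seeded downstream computation reproducible for a given Newick
string. Ultrametricity is checked to a relative tolerance of 1e-6.
Patristic distance is the sum of branch lengths along the tip-to-tip
path; on an ultrametric tree it equals twice the age of the pair's most
recent common ancestor. The Brownian-motion covariance `C[i,j]` is the
shared root-to-MRCA path length, so `d(i,j) = C[i,i] + C[j,j] −
2 C[i,j]` holds on every tree (a property test asserts this on 50
random trees). Polytomies are accepted on input but rejected wherever
the algorithm genuinely requires bifurcation (contrasts, the
variable-rates pruning), with an explicit error.

"Phylogenetic distance" for the partial-Mantel control means patristic
distance on the time tree — the standard and, on a fixed time tree, the
only tree-derived species-pair distance.

## Geometric morphometrics (`shapes`)

Generalized Procrustes analysis removes translation (centroids to the
origin), optionally scale (unit centroid size), and rotation, iterating
rotations against the running consensus until the consensus changes by
less than 1e-10 (at most 100 iterations; convergence in practice takes
2–3). Rotations are proper (no reflections), preserving chirality.
Because a Procrustes alignment is only defined up to a global rotation,
the converged dataset is put into a canonical orientation — principal
axes of the consensus, largest-magnitude coordinate per axis positive,
determinant +1 — so the output is invariant (to 1e-8) under any common
rigid motion plus scaling of the inputs. This canonicalization assumes
the consensus has non-degenerate principal axes, which holds for any
real landmark configuration.

Procrustes distance is the square root of the summed squared coordinate
differences after optimally superimposing one configuration on the
other (translation + proper rotation, with unit-size scaling matching
the upstream alignment); this is the partial Procrustes distance, the
post-superimposition Euclidean norm. Restricted to unit-size shapes it
satisfies the triangle inequality (checked on random triples).

The oral-jaw dataset is aligned as a whole-body configuration with
scaling ON, after which the four premaxilla landmarks are extracted and
re-centred only — no re-rotation, no re-scaling — so the premaxilla
retains its size and orientation relative to the body axes. Pairwise
oral-jaw distances are therefore computed without re-scaling, keeping
relative size as signal, while pharyngeal-jaw distances are computed on
unit-size shapes.

The pharyngeal jaw is digitized as a half-configuration; paired
landmarks are reflected across the least-squares plane through the
midline landmarks (the smallest-singular-vector normal), midline
landmarks are projected onto that plane, and the mirrored copies are
appended (K → |midline| + 2·|paired|; 27 → 42 for the anatomical
12-midline/15-paired partition, which is a dataset-level configuration,
not hard-coded). Mirroring the mirrored copies back recovers the input
to 1e-9. Collinear midline landmarks (undefined plane) raise an error.

Shape PCA is an SVD of centred, flattened species mean coordinates.
Axis signs are fixed by the largest-loading-positive rule, since PCA
signs are otherwise arbitrary. Metric traits (angles in degrees,
distance ratios, distances over centroid size, polygon-area ratios,
e.g. the proportion of bone area covered by teeth) are defined by
user-supplied landmark indices because the anatomical definitions are a
property of each dataset; all are invariant to rotation and
translation, and the size-normalized ones also to scale.

## Divergence comparison (`divergence`)

The partial Mantel statistic is the first-order partial Pearson
correlation of lower-triangle distance vectors. Permutations relabel
the first matrix only (rows and columns jointly), the test is
one-tailed for positive association, and the p-value uses the add-one
rule so it is never zero; the default is 999 permutations. A control
matrix with zero variance carries no information and degrades the test
to the simple Mantel statistic by an explicit bypass. For tiny matrices
an exhaustive mode enumerates all n! permutations and returns the exact
permutation p; this is the oracle route used in the tests, never the
default.

## Evolutionary correlations (`evocorr`)

Contrasts follow the classic pruning recursion: at each internal node,
contrast (xᵢ − xⱼ)/√(vᵢ + vⱼ), node value the inverse-variance-weighted
mean, and parent branch lengthened by vᵢvⱼ/(vᵢ + vⱼ). Contrast signs
are made deterministic by ordering children so the one containing the
lexicographically smallest descendant tip comes first; contrasts are
therefore invariant to tip input order.

Contrast correlations are computed **through the origin** with
df = n_contrasts − 1 and a two-tailed t-test; this is the standard
convention for contrasts (their expectation is zero under Brownian
motion) and is what makes a 234-species tree yield df = 232. The null
band is built from 1000 independent pairs of unit-rate BM traits
simulated on the same tree — operationalized as disjoint pairs, i.e.
1000 independent null correlations — summarized by the extreme range
(the headline summary) and the central 95% interval. Because contrasts
are standardized, this null depends only on the number of contrasts,
not the tree shape (a two-sample KS property test asserts this).

Phylogenetic two-block PLS: per block, the phylogenetic GLS mean
a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X is removed; the SVD of the evolutionary
cross-covariance R₁₂ = X₁ᶜᵀC⁻¹X₂ᶜ/(n−1) gives the paired axes of most
covariance; scores are the C^(−1/2)-transformed data (symmetric inverse
square root, eigenvalue floor 1e-12) projected on those axes, and
r_pls is their Pearson correlation. Significance comes from permuting
species rows of the transformed second block (add-one rule), matching
residual-randomization practice. On a star phylogeny C ∝ I and the fit
collapses to ordinary two-block PLS, which the tests assert to 1e-9.

## Variable-rates model (`ratemodel`)

Likelihood: traits are independent given the tree and a shared set of
rate scalars; trait k is multivariate normal with mean αₖ·1 and
covariance σ²ₖ·V(r), where V(r) is the BM covariance of the tree whose
branch lengths are multiplied by their relative rates (the product of
all scalars whose scope covers the branch; clade scalars multiply every
branch of the subtree). The density is evaluated by an O(n) pruning
decomposition — each contrast contributes a univariate normal term and
the root a final term for the GLS mean — which is algebraically exact
and is verified against a dense multivariate-normal oracle to 1e-8 on
trees of up to 12 tips.

Priors: α uniform (−1, 1) per trait; σ² uniform (0, upper) per trait
with dataset-level uppers (defaults 1e-4 for the oral jaw, 1e-3 for the
pharyngeal jaw — these uppers are in (My)⁻¹ units of squared trait
change per My); shift count truncated Poisson(λ = 1) with configuration
sets uniform over unoccupied branch×scope slots; shift magnitude
log-normal(0, 1.5²) truncated to (1e-3, 1e3). The magnitude and count
priors are documented, configurable stand-ins where the upstream
literature does not print its defaults. Both branch- and clade-scoped
scalars are supported; a flag disables clade scalars.

Sampler: Metropolis-Hastings with move mix 25% α slide (reflected at
the bounds), 25% σ² slide, 15% multiplicative log-normal walk on an
existing scalar (Hastings-corrected), 17.5% birth, 17.5% death. With a
prior uniform over unordered slot sets, the slot-choice factors cancel
between prior and proposal, leaving birth acceptance L-ratio·λ/(k+1)
and death L-ratio·k/λ. A prior-only run (likelihood disabled)
reproduces the truncated-Poisson shift-count prior (chi-square GOF in
the tests) — the standard correctness check for reversible-jump
acceptance ratios. Chains are numba-compiled and byte-reproducible
given (config, seed).

The desk-scale default chain is 2×10⁶ iterations, burnin 2×10⁵, thin
200 (9000 retained draws); the radiation-scale setting of 10⁹
iterations sampled every 10⁵ after a 10⁷ burnin is a cluster budget
reproduced in configuration only. ESS uses initial-positive-sequence
truncation, N/(1 + 2Σρₜ), capped at N; 200 is the adequacy yardstick,
flagged by callers rather than enforced. Bimodal posteriors (two rate
optima trading σ² against scalars) are handled by `split_posterior`:
per-trait σ² cutoffs assign each draw to the all-below or all-at-or-
above optimum, dropped draws are counted, and posterior probabilities
are fractions of the full sample; `summarize_rates` can also report
absolute rates (σ² × relative rate per draw, then averaged), which
reconcile the two optima.

## Rate correlations through time (`ratecorr`)

Branch age intervals are half-open, (parent age, child age], and the
window grid is anchored at the present with width 0.15 My; all branches
older than 8 My fall into one merged first window so every window holds
at least a handful of branches (7 is the flagging threshold). Overlap
testing is closed-open, preventing double counting at boundaries — a
branch ending exactly at a window's older bound is not in that window.
Branches enter windows unweighted (membership, not duration weighting).
Per-window Pearson p-values are reported raw and flagged at 0.05; no
multiple-testing correction is applied, keeping windows interpretable
individually. Windows with fewer than 3 branches have undefined r,
reported as missing. With a single window spanning the tree, the
windowed correlation equals the overall branch-rate correlation.

## Synthetic data (`synthetic_data`)

The generator emulates the structure of a ~10-My, ~234-species
lacustrine radiation: a pure-birth tree rescaled so the root age is
exact; joint Brownian motion of two 3-axis trait blocks whose
increments share a cross-block correlation ρ on matched axes (coupling
acts at the process level — on increments, not tip states — because
that is the quantity the contrast-based tests estimate); defaults of 5
specimens per species with i.i.d. Gaussian landmark noise (sd 0.005)
and random rigid motions plus scale to exercise the alignment. Named
scenarios: `coupled` (ρ = 0.9), `decoupled` (ρ = 0), `late_decoupled`
(ρ = 0.8 on branch segments older than 2 My, 0 on younger; branches
crossing the change age are split at it), and `shifted_clade` (a
planted multiplicative increment-variance shift on a named clade).
`simulate_branch_rates` draws per-branch log-normal relative rates with
the same epoch-dependent coupling, for exercising the windowed rate
correlation without an MCMC in front of it.

Landmark templates are a 4-landmark 2-D quadrilateral (premaxilla
stand-in, embedded in a 10-landmark "body" for the whole-skeleton
alignment) and a 21-landmark 3-D half-configuration (9 midline + 12
paired; smaller than the anatomical 27 for speed, configurable up to
12 + 15). Deformation bases are random orthonormal vectors orthogonal
to rigid translations.

What the generator does **not** emulate: anatomically realistic
deformations, digitization error structure beyond i.i.d. noise,
diversification slowdowns, or measurement covariance between the two
jaws from shared specimens. Passing tests therefore demonstrate the
statistical machinery under its stated assumptions, not the behaviour
of any particular empirical dataset.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen as the package's
own defaults: 234-tip trees and 1000 null pairs for the null band;
50-tip trees with 2×10⁶-iteration chains for shift recovery; 500
replicates for calibration checks (nominal 0.05 level accepted within
[0.03, 0.07]); 199–999 permutations for permutation tests. GPA
tolerance 1e-10; ultrametricity tolerance 1e-6 relative; inverse square
root eigenvalue floor 1e-12; ties in PCA/PLS orientation broken by
largest-magnitude-positive rules. Degenerate inputs (constant distance
matrices, zero-variance contrasts, collinear midlines, empty posterior
subsamples) raise explicit errors rather than returning NaN.

## Known limitations

- The variable-rates sampler is a single chain; no parallel tempering
  or marginal-likelihood estimation, and no claim of bit-compatibility
  with external implementations of the model.
- Traits within a jaw are modelled as independent given the tree and
  shared scalars (appropriate for orthogonal PC axes, not for raw
  correlated traits).
- The contrast machinery requires a strictly bifurcating tree.
- Mantel-type tests have known sensitivity to spatial/phylogenetic
  autocorrelation in the control matrix; the partial Mantel here
  reproduces the field-standard construction rather than remedying it.
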