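# Methods

`mdifuse` implements correlated Bayesian clustering of a shared set of n
genes across K heterogeneous datasets (Multiple Dataset Integration, MDI),
with posterior *fusion* analysis of the resulting allocations.  This note
records the model, the sampler, the numerical choices, what the synthetic
generator does and does not emulate, and known limitations.

## Model

Each dataset k is modelled by a finite Dirichlet-multinomial allocation
(DMA) mixture with N components — a finite approximation to a Dirichlet
process mixture in which N is only an upper bound on the number of
clusters: unneeded components simply stay unoccupied, so the number of
clusters is inferred, not fixed.  Gene i carries one allocation variable
c_ik per dataset.  Mixture weights are represented unnormalized: each
dataset has γ_ck ~ Gamma(α_k/N, 1) independently, whose normalization is
the usual symmetric Dirichlet(α_k/N) weight vector; α_k is the per-dataset
mass parameter, itself given a Gamma prior and inferred.

Datasets are coupled only through the allocations.  The joint prior for one
gene's label row (c_1..c_K) is proportional to

    prod_k γ[c_k, k]  ×  prod_{k<l} (1 + φ_kl · 1[c_k = c_l]),

so φ_kl ≥ 0 up-weights the probability that a gene takes the *same*
component label in datasets k and l.  φ = 0 recovers K independent
mixtures.  Component labels are global: component c means the same cluster
in every dataset, which is what makes label equality meaningful.  The
per-gene normalizing constant Z — the sum of the expression above over all
N^K label rows — appears to the power n in the joint prior and couples all
parameters.

Because each dataset keeps its own likelihood family, the coupling never
has to compare values across data types; it compares clustering structure
only.

## Component likelihoods

All families are collapsed: component parameters are integrated out and the
sampler only ever evaluates marginal and posterior-predictive densities
from sufficient statistics.

* **Multinomial** (categorical / binary data): independent per-feature
  Dirichlet-multinomial with pseudo-count 0.5 per category by default
  (Jeffreys-like; configurable).  Binary interaction or binding profiles
  are the two-letter special case.
* **Bag of words** (count data): a single shared word distribution per
  component; the component marginal is the Dirichlet-multinomial of the
  pooled count vector, pseudo-count 0.5 per word.  The multinomial
  coefficient is omitted in *all* marginals: items are distinguishable, the
  coefficient is constant in the allocations, and it cancels in every
  sampler ratio.  Absolute marginal values therefore depend on this
  convention (documented because the tests pin them).
* **Gaussian process** (time courses): all profiles in a component share
  one latent function drawn from a zero-mean GP with squared-exponential
  kernel, observed with i.i.d. Gaussian noise.  Profiles are standardized
  per gene (zero mean, unit variance; switchable).  Defaults: signal
  variance 1.0, length-scale = 1/4 of the time span, noise variance 0.25 —
  on standardized profiles these place the prior function scale at the data
  scale and let roughly a quarter of the variance be noise.  The three
  hyperparameters are shared across components within a dataset and updated
  once per sweep by joint random-walk Metropolis on the log scale
  (step 0.15, independent log-normal priors centred at the defaults with
  scales 1.0 / 0.5 / 1.0).

  The stacked covariance of m profiles on T shared time points is
  J_m ⊗ K + σ²I.  In the eigenbasis of the kernel matrix K the density
  factorizes over the T eigendirections into one-factor models, so a
  component's sufficient statistics are its item count, the per-direction
  sums, and the total sum of squares — add/remove/predict are O(T) instead
  of O((mT)³) Cholesky work.  Noise variance is floored at 1e-12; kernel
  eigenvalues are clipped at zero.

## Gibbs sampler

The Z^n factor in the joint prior is linearized with one auxiliary variable
v whose full conditional is Gamma(n, Z); marginalizing v over that
conditional restores Z^{-n} exactly.  Z itself is evaluated by expanding
the pairwise coupling product over subsets of dataset pairs: a subset S
contributes (prod of its φ's) times, for every connected component B of the
graph (datasets, S), the factor sum_c prod_{k∈B} γ_ck.  The induced
partition of each of the 2^{K(K−1)/2} edge subsets depends only on K and is
tabulated once; the per-state evaluation is a few vectorized reductions.
K is capped at 6 — the expansion grows as 2^{K(K−1)/2} and larger K is
rejected rather than approximated.  Z is multilinear in every γ_ck and
every φ_kl, and the workspace exposes those exact partial derivatives
(checked against finite differences of a brute-force N^K enumeration).

Per sweep, in order:

1. **v** ~ Gamma(n, Z).
2. **Allocations**: systematic scan (genes in index order within each
   dataset; a randomized-order flag exists), each c_ik drawn from
   p(c) ∝ γ_ck · prod_{l≠k}(1 + φ_kl 1[c = c_il]) · predictive(x_ik | c),
   with the gene removed from its component's statistics before scoring and
   re-added after the draw.
3. **Weights**: γ_ck ~ Gamma(α_k/N + n_ck, 1 + v ∂Z/∂γ_ck) — exact by
   multilinearity.  Derivatives are refreshed after every single draw
   (updating one γ entry changes the others' conditionals).  Draws are
   floored at 1e-150, far below anything that affects the posterior but
   high enough that K-fold products cannot underflow Z to an exact zero.
4. **Associations**: the exact conditional of φ_kl is
   φ^{a−1}(1+φ)^{ρ_kl} exp(−(b + v ∂Z/∂φ_kl)φ) with ρ_kl the
   label-agreement count and Gamma(a, b) the prior.  Binomially expanding
   (1+φ)^ρ makes this a finite mixture of Gamma(a+m, ·) densities,
   m = 0..ρ, which is sampled exactly in one shot.  (The superficially
   tempting Gamma(a+ρ, ·) draw is *not* the conditional of this model —
   the coupling contributes (1+φ)^ρ, not φ^ρ — and fails the
   joint-distribution test below.)
5. **Mass**: α_k is slice-sampled from
   p(α | γ) ∝ p(α) prod_c Gamma(γ_ck; α/N, 1).  Because the chain keeps the
   *unnormalized* weights, this — and not the normalized-Dirichlet form —
   is the exact conditional; the total weight sum carries information about
   α.  Stepping-out slice sampler, width 0.5, at most 100 expansions
   (bracket failure keeps the current value and logs a warning).
6. **GP hyperparameters**: one Metropolis proposal per time-course dataset;
   accepted moves rebuild the eigenbasis and rotate the sufficient
   statistics in place.
7. **Label-swap moves**: Metropolis proposals exchanging two component
   labels (weights, allocations and statistics together) inside a *subset*
   of datasets.  Within the subset every likelihood and weight-prior term
   is invariant; only coupling factors crossing the subset boundary and Z
   enter the ratio.  One single-dataset proposal per dataset plus K
   random-subset proposals are made per sweep.  Subset proposals matter:
   when the component correspondence drifts apart between two groups of
   datasets, a single-dataset swap can be blocked by strong partners on
   both sides of the split, while swapping the whole group at once is
   accepted.  The move leaves the posterior invariant by construction.

**Initialization.**  Allocations are seeded by per-dataset k-means into
min(8, N) groups, then the component labels are made to correspond across
datasets: datasets are visited along the maximum matched-overlap spanning
tree rooted at dataset 0 and each is Hungarian-matched to its already
aligned parent.  The tree matters: matching every dataset directly to
dataset 0 fails whenever the direct agreement between two distant datasets
is near chance (in the permutation design it decays toward chance with
dataset distance), because the correspondence is then only identifiable
transitively through high-agreement intermediates.  γ starts at 1/N, φ at
its prior mean, α at its prior mean, v at n/Z.  During burn-in only, every
50 sweeps the tree realignment is repeated on the current allocations
(weights and component statistics permuted along with the labels, so every
likelihood term is untouched).  This is an initialization aid, not part of
the transition kernel — the burn-in state is arbitrary and no snapshot is
taken before burn-in ends — and it deterministically repairs residual
cross-dataset correspondence drift before sampling statistics are
collected.

**Priors and defaults.**  α_k ~ Gamma(2, 4) (mean 0.5, favouring few
occupied components while allowing more); φ_kl ~ Gamma(1, 0.2) (mean 5,
weakly informative: admits both φ ≈ 0 (independence) and strong coupling).
Chain defaults are 2000 sweeps, burn-in 1000, thinning 5 — floor settings
for library-scale problems; all are configurable.  Snapshots are recorded
at iterations it with it > burn_in and (it − burn_in) divisible by the
thinning, giving ⌊(iterations − burn_in)/thinning⌋ snapshots.

**Correctness surface.**  The primary test is a Geweke-style joint
distribution check at tiny scale (n = 3, K = 2, N = 2, one binary feature):
forward simulation of (parameters, allocations, data) is compared with a
chain alternating the sampler's own conditionals and a data-refresh step;
agreement-count, occupancy, φ, α and data-mean statistics must agree within
Monte-Carlo error.  A second check fixes φ ≡ 0 and compares per-dataset
posterior co-clustering against an independently written collapsed-weight
single-dataset sampler.

## Posterior summaries

* **Fusion probability** of gene i across a dataset subset S (|S| ≥ 2):
  the fraction of snapshots in which c_ik is identical for all k in S.
  Monotone under subset growth by construction.  A gene is *fused* when the
  probability exceeds the threshold (default 0.5).
* **Fused clusters**: snapshots are restricted to the fused genes, labels
  taken from the reference dataset min(S) (a documented convention — fused
  genes agree across S in most but not all snapshots).  Every distinct
  sampled partition is scored by its posterior expected adjusted Rand index
  against the posterior similarity matrix (the Fritsch–Ickstadt pair-count
  form), and the argmax is returned; ties keep the first occurrence in
  chain order.  The candidate set is deliberately the sampled partitions
  only, not a greedy search over arbitrary partitions.  An empty fused set
  is a warning plus an empty report, not an error.
* **ARI** is the Hubert–Arabie adjusted Rand index
  (scikit-learn's implementation behind the package's function).
* **φ summary**: off-diagonal posterior means; the diagonal is undefined
  and reported as NaN, never as 0.

## Synthetic data

The flagship generator reproduces the six-dataset permutation design:
dataset 1 holds n = 100 time courses in 7 well-separated clusters; each
later dataset selects 25 rows of its predecessor at random and permutes the
gene names among them, leaving each profile attached to its cluster, so
consecutive datasets disagree on at most 25 gene labels and agreement
decays with dataset distance.  The published version of this design was
built on a real yeast cell-cycle subset; this package substitutes
parametric stand-ins — seven phase-shifted sinusoids (amplitude 2.0, period
80 min on a 17-point, 10-min grid) plus i.i.d. Gaussian noise (sd 0.3) —
chosen once so that a single dataset alone is clusterable almost perfectly
("easily distinguishable" clusters), which the tests assert (single-dataset
ARI > 0.9).  Cluster sizes are balanced up to rounding.

What passing on this stand-in shows: that the *procedure* — coupled
sampling, association estimation, fusion classification — behaves as
published under comparable cluster separability.  What it does not show:
robustness to the noise structure, uneven cluster sizes, or weak separation
of real expression compendia; those properties are not claimed.

Discrete analogues (categorical, sparse-Bernoulli "interaction-screen"
binary, and fixed-length bag-of-words views driven by the same labels, with
a Dirichlet concentration parameter controlling separation) exist to
exercise the discrete likelihoods; concentration → 0 makes clusters
near-deterministic.

## Numerical choices and degenerate inputs

* Z and its derivatives: block sums are re-summed from the cached
  per-component product table rather than updated by additive deltas —
  entries span hundreds of orders of magnitude and delta updates cancel
  catastrophically.
* Allocation draws use a max-shifted softmax and inverse-CDF sampling.
* n < 2 genes or a dataset with zero features is a hard error; constant
  features are kept (they contribute constants that cancel).
* Duplicate gene ids, ragged rows, non-numeric cells and non-increasing
  time headers are rejected at read time with the offending row/column
  named; views are aligned on the id intersection in first-view order, and
  dropped ids are logged.
* Default N is min(50, ⌈n/2⌉) when not specified.

## Problem sizes used in the shipped checks

The end-to-end experiment in the test suite and the acceptance script runs
the design above at K = 6, n = 100, N = 15, 2000 sweeps (burn-in 1000,
thinning 5, 200 snapshots); the joint-distribution check uses 20 000
forward draws against 20 000 transitions at n = 3; oracle equivalences run
on instances small enough for exhaustive enumeration (N^K label sums,
Bell(5) partitions, ≤ 3^6 outcome enumerations).  These sizes were chosen
as the smallest at which the statistics of interest are stable.

## Limitations

* K ≤ 6 by design of the exact Z expansion; no approximate regime is
  offered.
* No missing-data handling; profiles must be complete on a shared grid.
* No split-merge moves; multimodality across *partitions* (as opposed to
  label correspondence) is handled only by the standard collapsed scans.
* GP hyperparameters are shared across components within a dataset;
  per-component kernels are out of scope.
* Marginal likelihoods for model comparison, infinite (DP-limit) mixtures
  and variational approximations are out of scope.
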