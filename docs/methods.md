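# Methods

This note defines the statistical model behind `phylopred`, the
estimators the package implements, the numerical choices made, and the
known limits of the prediction intervals. Everything here is
self-contained; the simulators in `phylopred.simulate` generate every
dataset used by the test-suite and the examples.

## Model

Let a rooted, ultrametric phylogeny with `n` tips have the
variance–covariance matrix `C`: `C[i, j]` is the shared path length
(root to most recent common ancestor) of tips `i` and `j`, and
`C[i, i]` is the root-to-tip depth. A continuous trait `x` evolving by
Brownian motion with rate `sigma^2` from root state `mu` is then
multivariate normal:

```
x ~ Normal(mu * 1, sigma^2 * C(lambda))
```

Pagel's lambda in `[0, 1]` rescales only the off-diagonal entries of
`C`; `lambda = 1` is pure Brownian motion and `lambda = 0` removes all
phylogenetic covariance (a star phylogeny). On an ultrametric tree the
same transform can be applied to branch lengths directly: internal
branches are multiplied by lambda and each pendant branch is stretched
so every tip keeps its original depth. `Phylogeny.rescale_lambda`
implements this; `apply_lambda` does the matrix version, and the two
commute (`tests/test_tree.py` checks this).

## Signal estimation (`phylopred.signal`)

For fixed lambda, the mean and rate have closed-form maximum-likelihood
solutions

```
mu_hat     = (1' C^-1 1)^-1 1' C^-1 x
sigma2_hat = (x - mu_hat 1)' C^-1 (x - mu_hat 1) / n        (ML divisor n)
```

so lambda is found by profiling: evaluate the profile log-likelihood on
a 26-point grid over `[0, 1]`, then refine with bounded Brent search
(`xatol = 1e-8`) around the grid optimum, re-checking both boundaries.
If two local optima lie within 2 log-likelihood units a warning is
emitted. A likelihood-ratio test against `lambda = 0` (chi-squared,
1 df) gives `lrt_p`. All solves use Cholesky factorizations; matrices
are never inverted explicitly.

## PGLS regression (`phylopred.pgls`)

With design matrix `X` (intercept prepended) and residual covariance
`V = sigma^2 C(lambda)`:

```
beta_hat = (X' V^-1 X)^-1 X' V^-1 y
```

Coefficient standard errors use the unbiased residual rate
`RSS_gls / (n - m - 1)`; the reported log-likelihood is the ML one.
Lambda for the residuals is estimated by profiling the GLS likelihood
the same way as in the signal fit. `model_p` is an F test against the
intercept-only model at the fitted lambda. At `lambda = 0` PGLS reduces
to ordinary least squares exactly (machine precision, tested against
`statsmodels`).

### Prediction for new species

`PGLS.predict` is the best linear unbiased predictor for a species with
covariates `x0` and phylogenetic cross-covariance `v0` to the training
species (kriging on the tree):

```
y0_hat = x0' beta_hat + v0' V^-1 (y - X beta_hat)
var    = sigma^2 [ (c00 - v0' V^-1 v0) + u' (X' V^-1 X)^-1 u ],
u      = x0 - X' V^-1 v0
```

The variance carries both the conditional Brownian variance and the
coefficient-estimation uncertainty; at `lambda = 0` it reduces to the
classical OLS prediction variance `s^2 (1 + x0' (X'X)^-1 x0)`.

## Ancestral states (`phylopred.ancestral`)

Internal-node states are the joint generalized-least-squares
reconstruction: the states minimizing

```
sum over branches of (x_child - x_parent)^2 / branch_length
```

which is a sparse weighted graph-Laplacian system (the rate cancels, so
no sigma^2 is needed). This equals the standard GLS/ML reconstruction
for Brownian motion. The solve is `scipy.sparse` Cholesky-free
(`spsolve`) and is exercised against a dense least-squares oracle in
the tests.

## Imputing unmeasured tips

To predict trait values for species on the tree but missing from the
data, the imputer:

1. estimates lambda and sigma^2 from the measured species (or uses
   fixed values), and rescales the tree by lambda;
2. prunes the tree to the measured species and reconstructs all
   ancestral states;
3. locates, for each unmeasured species `u`, its anchor: the first
   ancestor `A` of `u` (walking rootward in the full tree) that has
   measured descendants. On the pruned tree `A` is either a surviving
   node or a point on a branch, in which case the anchor state is
   linearly interpolated between the reconstructed states flanking that
   branch (the Brownian-bridge conditional mean);
4. predicts `x_u` = anchor state, with a 95% interval

```
x_u +/- 1.96 * sqrt(t * sigma2_hat)
```

where `t` is, by default (`t_mode="path"`), the elapsed time from the
anchor down to the tip (`depth_u - depth_A`); `t_mode="pendant"` uses
the pendant branch length instead. For an anchor above the pruned root
the root state is used with `t = depth_u - depth_A` unchanged.

The point prediction is provably the exact conditional expectation of
the Gaussian model given the measured tips (verified against a dense
conditional-normal oracle in `tests/test_ancestral.py`).

### Interval calibration

The interval above accounts only for Brownian divergence over `t`. It
deliberately does **not** propagate the uncertainty of the anchor state
itself, which is a reconstruction from finitely many relatives. The
full conditional variance of `x_u` given the measured tips is
`sigma^2 (c_uu - v' C_mm^-1 v)`, which is generally larger than
`sigma^2 t`; in dense designs the omitted anchor-variance term is
material.

Consequence, quantified by simulation with known sigma^2 and exact
conditional variances: in a leave-one-out design on a 200-tip pure-birth
tree with `lambda = 1`, the achievable coverage of the `t`-only interval
is structurally about 88%, not the nominal 95% (about 87.8–88.1% across
trees in our computations; the empirical jackknife with estimated
parameters lands at about 87.5%). The regression (kriging) interval of
`PGLS.predict`, which does carry the full prediction variance,
calibrates at about 95–96% in the same designs. Users who need
calibrated intervals for tip imputation should treat the `t`-only
interval as a lower bound on uncertainty; the point predictions are
unaffected (they are exactly optimal under the model).

## Validation (`phylopred.validation`)

`jackknife_phylo` removes each measured species in turn, refits lambda
and sigma^2 on the remainder (`refit=True`, the default; `refit=False`
reuses full-sample estimates), predicts the held-out species, and
reports the percentage of species inside their 95% interval and the
median absolute deviation in units of the trait's sample standard
deviation. `jackknife_regression` does the same for the PGLS predictor
on complete cases.

## Evolutionary correlations (`phylopred.evolcorr`)

For traits `X` (n species by p traits) the evolutionary rate matrix is

```
R = (X - 1 a_hat)' C(lambda)^-1 (X - 1 a_hat) / (n - 1)
```

with `a_hat` the vector of phylogenetic means; the evolutionary
correlation is `r_ij = R_ij / sqrt(R_ii R_jj)`. Lambda can be fixed or
estimated per pair by maximizing the matrix-normal likelihood with the
means and rate matrix profiled out. Significance is a two-sided t test
with `n - 2` df; `correlation_matrix` is pairwise-complete (so it may
be non-positive-semi-definite, which triggers a warning) and returns a
significance mask at a configurable alpha (default 0.1; type-I error of
the mask is checked by simulation in the acceptance tests).

## Simulators (`phylopred.simulate`)

* `simulate_yule_tree`: pure-birth tree; with `k` extant lineages the
  waiting time to the next split is `Exponential(k * birth_rate)`, the
  splitting lineage is uniform, and one more exponential interval is
  appended after the n-th lineage so the tree ends between events.
* `simulate_bm_traits`: tips drawn `Normal(root, sigma^2 C(lambda))`
  via Cholesky; an optional trait correlation matrix induces correlated
  evolution (Kronecker structure); `measured_fraction < 1` masks a
  fixed number of tips per trait, missing completely at random.
* `simulate_pgls_data`: i.i.d. normal predictors plus a lambda-Brownian
  residual; the generating parameters travel on the returned table as
  `sim_truth`.

All randomness flows through a single `numpy.random.Generator`, so
every fixture is reproducible from one integer seed.

## Numerical choices and default scales

* Dense linear algebra through Cholesky factorization with a
  `1e-10`-jitter retry; explicit inverses only in test oracles.
* Trees are stored as preorder arrays (`parent[i] < i`, contiguous
  subtree ranges), giving O(1) ancestor tests and a vectorized
  block-fill of the covariance matrix; the full-tree covariance is
  cached and submatrices are extracted for repeated (jackknife) use.
* Ultrametricity tolerance: relative depth spread `1e-6`.
* Default problem sizes used in the statistical tests — 200–300 tips,
  50 replicate traits — were chosen so the whole suite runs on a
  laptop-class machine in minutes while keeping Monte-Carlo error well
  below the tested tolerances.

## Limitations

* Continuous traits only, Brownian/lambda models only (no
  Ornstein–Uhlenbeck, no early-burst), strictly bifurcating or
  multifurcating rooted trees with branch lengths.
* The tip-imputation interval understates uncertainty by design (see
  "Interval calibration" above).
* Pairwise-complete correlation matrices are not guaranteed positive
  semi-definite.
* No measurement-error model: observed tip values are taken as exact.
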