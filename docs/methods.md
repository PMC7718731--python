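# Methods

## Model

For `n` genotyped individuals, `t` traits and `p` loci, the package fits
the multi-trait spike-and-slab regression

    y_i = mu + sum_j m_ij D_j beta_j + e_i,        e_i ~ N(0, R)

with genotype covariates `m_ij` in {0, 1, 2} (minor-allele counts, not
centered — the intercept `mu` absorbs the mean), per-locus effect vector
`beta_j ~ N(0, G)`, and `D_j = diag(delta_j)` holding per-trait inclusion
indicators.  Over `t` traits a locus can affect any of the `2^t` trait
combinations; the combination probabilities `Pi` carry a uniform
Dirichlet prior, and `R`, `G` carry inverse-Wishart priors written as
`IW(S * nu, nu)` so that `S * nu / (nu - t - 1)` is the prior mean.

The structural variant embeds a recursive (acyclic) system among traits:

    y_i = Lambda y_i + mu + sum_j m_ij D_j beta_j + e_i

Writing `Lambda* = I - Lambda` turns this into a regression on the
working response `Lambda* y_i`.  Identifiability of the structural
coefficients requires a diagonal `R`.  Because the system is recursive,
`det(Lambda*) = 1`, the Jacobian drops out of the likelihood, and the
vector `lambda` of nonzero entries of `Lambda` has the exact normal full
conditional

    V   = (sum_i Y_i' R^-1 Y_i + I/tau^2)^-1
    hat = V (sum_i Y_i' R^-1 w_i + 1 lambda0 / tau^2)

with `w_i = y_i - mu - sum_j m_ij alpha_j` and `Y_i` the sparse matrix
satisfying `Lambda* y_i = y_i - Y_i lambda`.  `lambda` is drawn jointly
as one multivariate-normal block.  The prior mean `lambda0` and variance
`tau^2` default to 0 and 1; `tau^2` is a fixed tuning parameter, not
sampled.

Convention: `Lambda[k, l]` multiplies trait `l`'s phenotype in trait
`k`'s equation, i.e. a one-unit increase in trait `l` moves trait `k` by
`Lambda[k, l]`.  Support vectors list positions `(k, l)` in sorted
order.

## Gibbs sampler

Update order per sweep, fixed: `mu` -> marker effects -> `G` -> `R` ->
`Pi` -> `lambda` (structural model only), with the working response
refreshed immediately after the `lambda` draw so every other conditional
sees the current structure.  One seeded `numpy` Generator drives the
whole chain; the marker sweep consumes pre-generated uniform/normal
arrays, which makes chains bit-reproducible regardless of the compiled
code path.

Marker effects are updated by single-site Gibbs (per locus, per trait):
the indicator is drawn from its Bernoulli full conditional with the
effect integrated out under its conditional prior
`beta_jk | beta_j,-k ~ N(m0, v0)` derived from `G`, then the effect is
drawn from its normal full conditional (included) or the conditional
prior (excluded).  This costs O(t) per locus instead of the O(2^t) of
full label enumeration and has the same stationary distribution; the
test suite validates it against exact enumeration of all labels on a
small instance.  The `G` update accumulates `beta_j` over loci with at
least one nonzero indicator (`IW(S_b nu_b + sum beta beta', nu_b + |J|)`),
following the convention of this model family.

Two compiled kernels implement the sweep: a residual-space version
(O(n) per visit, no extra memory) and a marker-space version that
precomputes `M'M` and maintains the right-hand sides under rank-one
corrections (O(p t) per *changed* effect).  The marker-space path is
used automatically for `p <= 2048`; both produce identical draws from
identical random inputs, which is asserted in the tests.  Residuals are
rebuilt from the current (sparse) set of included effects at the start
of every sweep, so incremental floating-point drift cannot accumulate
across sweeps.

Default hyperparameters (the source analyses do not state them):
`nu_e = nu_b = t + 2`; `S_e` is chosen so the prior mean of `R` is half
the sample phenotypic covariance; `S_b` so the implied prior mean of the
total genetic covariance — per-effect covariance times
`sum_j 2 f_j (1 - f_j)` times the prior inclusion expectation 0.5 — is
the other half.  Chain defaults are 50,000 sweeps, 10,000 burn-in,
thinning 10; all are configuration-exposed and should be tuned to the
data set.

## Causal structure search

1. Fit the exchangeable (full-`R`) model and retain posterior samples of
   the residual covariance.
2. For every trait pair `(i, j)` and every subset `h` of the remaining
   traits, compute the residual partial correlation per sample (from the
   precision of the `(i, j, h)` submatrix) and declare conditional
   independence when the 0.9 highest-posterior-density interval contains
   zero.  HPD intervals are the empirical shortest window over sorted
   samples containing `ceil(mass * m)` points, ties broken toward the
   lower start.  All subsets are tested by default (`t` is small in the
   intended applications); a `max_cond` knob bounds the subset size for
   larger `t`.
3. Pearl–Verma IC: connect pairs never separated; orient v-structures
   `i -> k <- j` when `k` lies in no separating set; close under Meek
   rules R1–R3.  R4 is omitted because it only fires under background
   knowledge, which the module does not accept.  Conflicting forced
   orientations are logged and the edge left undirected rather than
   aborting, since the output is an equivalence class anyway.

`enumerate_orientations` lists every acyclic, v-structure-preserving
orientation of the undirected edges — the Markov equivalence class —
as support patterns for `Lambda`; the user picks the member to fit,
typically with external biological knowledge.

## Effect decomposition and window inference

Per retained sample, using the joint draw of `Lambda` and `alpha`
(posterior dependence between the two makes plugging in posterior means
inaccurate): direct = `alpha_j`; indirect = `sum_{rho=1}^{t-1}
Lambda^rho alpha_j`; overall = `(I - Lambda)^-1 alpha_j` = direct +
indirect.  Traits with no inbound causal edge have identically zero
indirect effects.

Windows are non-overlapping blocks of consecutive markers in map order
(default 100 SNPs) that never span chromosome boundaries — the window
count is therefore map-dependent and logged.  For window `w` and one
sample, `a_w = M_w alpha_w` per effect type; its variance uses the
population form (divide by `n`, no Bessel correction, exactly as the
estimator is defined); the denominator `sigma_a^2` is the variance of
the genetic values from *overall* effects of *all* markers.  The ratio
`q_w` is not clamped: it can exceed 1 when a window's genetic values
anti-correlate with the remainder.  WPPA is the fraction of samples with
`q_w` strictly greater than `T = 1/N` (`N` = total windows, one shared
`T` for all effect types); windows with WPPA at or above 0.8 are
declared significant, which bounds the proportion of false positives
among declarations below 0.2.

Pleiotropy proportions: for direct effects, the posterior mean of `Pi`
per label; for overall effects, a locus counts toward trait `k` in a
sample when it has an included direct effect on `k` or on any trait with
a nonzero `Lambda` path into `k` (reachability through the sampled
structure), and label frequencies are averaged over samples.

## Synthetic data

The generator emulates a two-trait benchmark design: binomial genotypes
at per-marker allele frequencies uniform on (0.05, 0.5) (an optional
mixing parameter copies adjacent genotypes to mimic first-order LD,
default off); QTL positions uniform without replacement among the `p`
markers (causal variants are genotyped); effect magnitudes from a
Gamma(shape, scale = 1) with shape in {0.18, 1.48, 3.0} and QTL counts
in {30, 90, 300}; half the QTL affect both traits directly (scenario 1)
and half only trait 1 (scenario 2); trait 1 affects trait 2 with
structural coefficient 1.0; per-trait heritability 0.5.

Decisions where the design was open:

- Effect signs are randomized (+/- with equal probability) since a
  nonnegative gamma draw would make genetic values systematically
  directional.
- Heritability is imposed per trait on its own structural-equation
  scale: `var(e_k) = var(u_k) (1 - h2)/h2` with `u_k = M alpha_k`.  For
  a purely downstream trait (no direct QTL, e.g. a scenario-2-only
  configuration) the residual is scaled off the inherited causal signal
  `var(Lambda_k y)` instead, so indirect-only designs remain simulable.
- Window-level truth: a window is truly associated through direct
  effects iff it contains a QTL with a nonzero direct effect on the
  trait, through indirect effects iff it contains a QTL affecting a
  causal ancestor, overall = either.

What the generator does not emulate: linkage disequilibrium structure of
real panels (beyond the optional first-order mixing), population
structure and relatedness, dominance/epistasis, and multi-allelic or
imputed dosages.  Passing recovery tests on this generator therefore
demonstrates correctness of the samplers and scoring, not robustness to
confounding by structure in real data.

## Evaluation

Window scores (WPPA here, any per-window statistic in general) are
scored by the partial area under the empirical ROC up to a false
positive rate of 0.05, rescaled by the area of the continuous diagonal
over that strip (0.05^2/2 = 0.00125) so the scale reads "multiples of a
random classifier".  The ROC is the standard right-continuous empirical
curve with tie groups moved simultaneously (trapezoids give tie groups
diagonal segments), matching the semantics of the common R
implementations, and is verified against a brute-force threshold sweep.
One consequence worth knowing: at a finite number of negative windows
the *expected* staircase area of a random classifier sits slightly above
the diagonal — with `neg` negatives and `K = 0.05 * neg` grid steps the
expected rescaled value is `K(K+1)/2 * pos/(neg+1) / (pos * neg *
0.00125)`, about 1.19 at 100 negatives and approaching 1 as windows
grow.  The rescaling constant is the conventional diagonal, not this
finite-sample mean.  Effect types that cannot exist for a trait (e.g.
indirect effects on a source trait) are reported as not-applicable
rather than scored.

## Problem sizes used in the shipped tests

The bundled recovery experiment uses n = 500 individuals, p = 1000
markers, 30 QTL with shape 0.18, and 20,000-sweep chains across 20
replicates (10 replicates in the acceptance script), with 10-SNP
windows so that the windows-per-QTL ratio is comparable to a
genome-scale panel scored with 100-SNP windows.  These sizes were chosen
so the whole suite runs on a single CPU in minutes while leaving the
posterior for `lambda` well resolved.

## Known limitations

- Only an overall mean is supported as a fixed effect; additional
  covariates are out of scope.
- Simultaneous (cyclic) structural systems are rejected; `tau^2` is
  fixed, not sampled.
- The loader accepts CSV and PLINK .bed/.bim/.fam (additive minor-allele
  coding, column-mode imputation at most); VCF and dosages are out of
  scope.
- The IC step's decisions inherit the Monte-Carlo error of the residual
  covariance samples; short chains can flip HPD decisions near zero.
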