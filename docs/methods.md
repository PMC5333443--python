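# Methods

## Scope and model

`seqvpc` estimates, tests, and bounds per-feature heritability for
high-throughput sequencing counts measured on panels of genetically
identical replicates — typically recombinant-inbred (RI) strains, where the
only systematic factor shared within a group is genotype. Classical
heritability is the intra-class correlation (ICC) of a Gaussian one-way
random-effects model; read counts are non-Gaussian, so the package works
with the variance partition coefficient (VPC),

    VPC = Var(E(y | strain)) / [ Var(E(y | strain)) + E(Var(y | strain)) ],

which reduces to the ICC in the linear case and remains well defined for
generalized linear mixed models.

Three observation models are fitted per feature g, all with a log link and
a strain random intercept `log mu_gs = alpha_g + b_gs`, `b_gs ~ N(0, sigma2_g)`:

1. **NBMM** — negative binomial, `Var = mu + phi * mu^2`. Requires
   integer input, so normalized counts are rounded (half away from zero).
   Closed-form VPC:
   `(e^s2 - 1) / (e^s2 - 1 + phi e^s2 + e^(-alpha - s2/2))`. It is bounded
   above by `(e^s2 - 1)/(e^s2 - 1 + phi e^s2)`, with limit `1/(1 + phi)` as
   `s2 -> inf`: an overdispersed feature cannot reach VPC 1 under this
   model, so results carry the bound and no rescaling is applied (rescaling
   would change the estimand).
2. **CPMM** — Tweedie compound Poisson with power `1 < p < 2`,
   `Var = phi * mu^p`; continuous on (0, inf) with a point mass at 0, so it
   accepts non-integer normalized counts directly. VPC:
   `(e^s2 - 1) / (e^s2 - 1 + phi e^((p-2) alpha + (p^2/2 - 1) s2))`, upper
   bound 1.
3. **LMM on transformed data** — a Gaussian one-way model on VST- or
   voom-transformed values; VPC = `s2_g* / (s2_g* + s2_eps*)`.

The VPC is zero iff `sigma2 = 0` and strictly increasing in `sigma2`
(property-tested); `solve_sigma2_for_vpc` inverts it by bracketed root
finding on `sigma2 in [0, 60]`, computing ratios in log space to avoid
overflow, and reports the attainable supremum when a target is infeasible.

## Estimation

The one-way structure factorizes the marginal likelihood over strains into
one-dimensional integrals. Each is evaluated by adaptive Gauss–Hermite
quadrature: a safeguarded Newton search finds the per-strain conditional
mode of the integrand (the objective is strictly concave in the random
effect for all three families), and 25 nodes (default) are recentered and
rescaled at the mode. Against a 4001-point trapezoid oracle the quadrature
is accurate to ~1e-10 even with a single observation per strain, and 25- vs
61-node results agree to < 1e-4 across the test grid.

Estimation is maximum likelihood throughout — the boundary test below
requires ML rather than REML — via Nelder–Mead over
`(alpha, sqrt(phi), sqrt(sigma2))` for the NB and
`(alpha, sqrt(phi), z, sqrt(sigma2))` for the CP model, where
`p = 1.01 + 0.98 / (1 + e^(-z))`. Square-root parameterizations keep the
variance components non-negative while leaving the `sigma2 = 0` boundary
reachable; estimates below 1e-8 are reported as exactly 0. Starting values
are robust per-strain moments: the intercept from the mean of per-strain
log means (the log of the grand mean is biased up by `e^(s2/2)` and by
heavy tails), dispersions from medians of per-strain moment estimates, and
`sigma2` from the between-strain variance of log strain means (floored at
1e-4). Because the logit map for `p` has flat tails, a simplex can stall
near `p = 2`; fits whose power lands outside (1.08, 1.92) are restarted
from `p in {1.3, 1.7}` with a moderate dispersion and the best likelihood
kept. Convergence uses simplex-size 1e-4 and likelihood 1e-6 tolerances
with a perturbed-restart fallback.

Null (`sigma2 = 0`) fits exploit that both families are
exponential-dispersion families: the intercept MLE is `log(ybar)` for any
dispersion, leaving a 1-D (NB) or 2-D (CP) dispersion optimization. After
an alternative fit the null likelihood is compared and the alternative
refitted from the null optimum if it is lower, so the likelihood-ratio
statistic is never negative. Drivers that only need point estimates can
skip the null fit (`fit(compute_null=False)`).

### Numerical kernels

The NB log-pmf, the Tweedie log-density and the quadrature run as
numba-compiled kernels. Given the dispersion parameters, each strain's
likelihood depends on the data only through the replicate count and sum, so
a quadrature node costs O(1). The Tweedie density's series over the latent
Poisson count is summed in a window around its maximizing index until terms
fall 37 log-units below the peak (exact for all reported values: it matches
a scipy Poisson-gamma convolution oracle to 1e-13 on the test grid, and
`phi = 0` in the NB is evaluated as the exact Poisson limit). Two
optimization-only approximations keep large simulation studies fast, and
the final log-likelihood is always recomputed exactly at the optimum:

* for features with > 48 positive observations the series term is
  interpolated in log y with a 24-node Chebyshev fit (abs. error <= 1e-4 on
  the worst tested feature, usually ~1e-8);
* when the maximizing series index exceeds 200 (tiny `phi` excursions of
  the optimizer) the window sum is replaced by its Laplace approximation
  over the index (relative error O(1/k), verified <= 7e-8 at k = 400).

## Testing heritability

`H0: sigma2 = 0` lies on the parameter-space boundary, so the LRT statistic
is asymptotically a 50:50 mixture of a point mass at 0 and chi-square with
1 df; `p = 1` at statistic 0 (the mixture's atom; the convention matters
for rank-based downstream use) and `0.5 * P(chi2_1 > stat)` otherwise.
Multiplicity is handled with Benjamini–Hochberg q-values. On null NB data
(50 strains, 3 replicates) the empirical size at the 5% level is ~0.03–0.04
— slightly conservative, matching the published behavior of the NB fit —
while the CP fit on the same (misspecified) data inflates to ~0.12.

## Confidence intervals

Percentile parametric bootstrap (B = 200 by default, minimum enforced by
the tail resolution): simulate B replicates of the feature from the fitted
family with the original strain design, refit, and take the empirical
2.5/97.5 percentiles of the refitted VPCs. Three routes: NB-refit, CP-refit
and the **VST hybrid**, which simulates from the fitted NB model but refits
each replicate with the VST + LMM pipeline, freezing the dispersion trend
estimated on the original dataset (a one-feature "dataset" cannot support
trend estimation, and re-estimating it per replicate would be circular).
The hybrid is ≳5x faster than GLMM refitting (asserted as a relative
runtime property in the tests). Refit failures are excluded with one
perturbed retry; a failure rate above 20% raises an error rather than
returning a silently distorted interval.

## Normalization and transformations

* **Size factors**: median-of-ratios against per-feature geometric means,
  computed on features positive in every sample and centered to geometric
  mean 1. Features failing the positivity requirement are normalized but do
  not influence the factors. Filtering (default: at least 5 samples with at
  least 10 counts) precedes everything.
* **Rounding** for the NB model is half-away-from-zero, stated explicitly
  because "nearest integer" is ambiguous at .5.
* **VST**: per-feature method-of-moments dispersions
  `max(0, (s^2 - m)/m^2)` are pooled into a trend `a(mu) = a0 + a1/mu`
  (non-negative least squares on features with mean > 1, one 10%-trimmed
  refit), and the closed-form antiderivative of the reciprocal square-root
  NB variance with that trend,
  `log2((1 + a1 + 2 a0 n + 2 sqrt(a0 n (1 + a1 + a0 n))) / (4 a0))`,
  is applied — strictly increasing and asymptotically `log2(n) + const`.
  With `a0 = 0` the Poisson-scale `2 sqrt(n / (1 + a1))` is used.
* **voom**: `log2((y + 0.5) / (L + 1) * 1e6)` with effective library size
  `L_j = factor_j * exp(mean(log column totals))`; the mean–variance trend
  is a lowess fit of root residual standard deviations against mean
  log-counts (residuals from the one-way strain design), inverted to
  per-observation precision weights. Whether the original voom-LMM analyses
  used these weights downstream is not documented; the LMM here fits
  voom values unweighted by default, with weighted fitting available.
  Both transforms are dataset-level operations; single-feature
  transformation is refused.

The LMM itself is fitted by profiling the likelihood down to the variance
ratio `gamma = sigma2_g / sigma2_eps` (per-strain block inverses are
rank-one updates; with precision weights the residual variance is scaled
per observation), optimizing over `log gamma`, and comparing against the
`gamma = 0` boundary. ML and REML are both available; ML feeds the LRT and
is the default report for cross-method comparability. Balanced-design ML
estimates match the closed-form ANOVA solution to 1e-6 in the tests.

## Synthetic data and the simulation studies

The generator emulates an RI expression panel: S strains, R_s replicates,
per-feature `(alpha, phi[, p], sigma2)`, counts drawn NB or CP ("NB-sim" /
"CP-sim") with strain effects redrawn per feature; features are
independent. Samplers use the Poisson-sum-of-gammas representation for the
CP and numpy's negative binomial (Poisson at `phi = 0`). All drivers take
one integer seed; per-replicate generators are spawned via SeedSequence and
recorded in the report manifest, so every report is bit-reproducible.

Default parameter distributions (the study conditions; the originals were
estimated from data not distributed here):
`alpha ~ U(1, 8)`; `phi ~ LogNormal(log 0.5, 0.8^2)` truncated to
[0.01, 5]; `p ~ U(1.2, 1.8)`; `sigma2 ~ U(0, 5)`; 10% null features
(`sigma2 = 0`) and 10% high-heritability features (`phi = 0.05`,
`sigma2 ~ U(2, 5)`). These magnitudes span what filtered small-RNA count
data exhibit. A fixed-seed synthetic "miRNA-like" table (881 features, 59
strains, 57x3 + 2x2 replicates) stands in for parameters estimated from a
real panel; the type-I/power study resamples from it with replacement.

Study drivers reproduce the five simulation designs: (I) per-cell RMSE over
a grid `alpha in {1,3,5,7}`, `phi in {0.1,0.5,1,2}`, `p in {1.2,1.5,1.8}`
with `sigma2 ~ U(0, sigma2_max)`, `sigma2_max in {1, 5}`, S=50, R=6;
(II) whole-dataset bias/RMSE/AUC at S in {25, 50}, R=3; (III) datasets from
the miRNA-like table; (IV) size and power of the boundary LRT at
`sigma2 in {0, 0.1, 0.25, 0.5, 0.75, 1}`; (V) bootstrap coverage at true
VPC {0.2, 0.5, 0.8}, with the strain variance solved exactly from the
generating family's VPC. The simulation-V base parameters are
`alpha = 2, phi = 0.1` (NB; `phi < 0.25` is required for VPC 0.8 to be
attainable under the NB bound) and `alpha = 2, phi = 0.5, p = 1.5` (CP).
Feature counts, strain counts and bootstrap B are arguments everywhere;
the problem sizes used by the test suite and the acceptance script (e.g.
100–200 features per grid cell, 500–1000 features per dataset study,
G=100/B=100 for coverage) are stated in their reports.

## What the synthetic studies do and do not show

The generators match the models' own assumptions: independent features,
i.i.d. strain effects, no batch or library-size structure (unit size
factors), no zero inflation beyond what NB/CP produce, and no
strain-relatedness (kinship) structure. Passing tests therefore demonstrate
correctness of estimation, testing and intervals under the stated models
and robustness across the declared parameter ranges — not performance under
real-data artifacts such as batch effects, correlated features, or
mapping noise. Known behaviors worth flagging:

* NB-fit VPC estimates in the lowest-expression grid corner
  (`alpha = 1`, mean count ~2.7, `phi = 0.1`) carry RMSE ~0.08: the VPC
  there is dominated by the shot-noise term `e^(-alpha - s2/2)`, and such
  features would largely fail the default expression filter on real data.
  The VST estimator is weakest in the same corner (RMSE up to ~0.21).
* CP-fit on NB-generated data overestimates the VPC (and its LRT
  over-rejects, size ~0.12 at nominal 0.05); with `alpha = 2, phi = 0.1`
  and true VPC 0.8 the bias is ~+0.06, which caps its bootstrap coverage
  near 80% at interval lengths ~0.2. NB-fit and VST are the robust choices
  under misspecification; CP-fit intervals excel when the data are CP.
* Power of the boundary LRT depends strongly on the expression-level
  distribution; under the default table it reaches ~0.99 at `sigma2 = 1`
  (S=50, R=3).

## Limitations

Intercept-only models (no covariates or batch terms); i.i.d. strain
effects (no kinship matrix); Tweedie power restricted to (1.01, 1.99);
integer rounding required for the NB route on normalized data; transforms
require the whole dataset. The bootstrap is percentile-based; no BCa
correction is attempted.
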