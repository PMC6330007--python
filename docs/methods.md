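# Methods

This note documents the statistical model behind `vqtlkit`, the
conventions the implementation commits to where several reasonable
choices exist, what the simulation generators do and do not emulate,
and the numerical details that determine reproducibility.

## The Bayesian test for heteroskedasticity (BTH)

For trait vector `y` and covariate `x` over `n` samples the model is

    y_i ~ Normal( beta0 + beta * x_i ,  sigma2 * alpha^(-x_i) )

The variance is an exponential (hence monotone and positive) function
of the covariate; `alpha = 1` recovers homoskedasticity. Assumptions:
Gaussian noise; a continuous or ordered covariate; monotone variance
effects. These buy power relative to the assumption-free Levene family
and make the test applicable to dosages and continuous covariates, at
the price of sensitivity to distributional misspecification — which
the trait-distribution classifier (below) is designed to catch.

Priors and hyperparameters:

| parameter | prior | default | role |
| --- | --- | --- | --- |
| beta (mean effect) | Normal(0, 1/gamma) | gamma = 1 | integrated out in closed form |
| sigma2 (baseline variance) | InvGamma(theta1, theta2) | theta1 = 1, theta2 = 2 | weakly informative, mean 2 |
| log alpha (variance effect) | Cauchy(x0, nu) | x0 = 0, nu = 5 | heavy-tailed, centered at no effect |
| beta0 (intercept) | flat (improper) | — | shared by both hypotheses |

The Bayes factor compares `alpha` free against the *point* null
`alpha = 1` (not a narrow prior around it). Computation proceeds in
two stages:

1. **Closed-form marginalization of beta.** With observation
   precisions `w_i = alpha^{x_i} / sigma2` and residuals
   `r_i = y_i − beta0`, Gaussian conjugacy gives
   `log p(y | beta0, sigma2, alpha) = −n/2·log 2π + ½·Σ log w_i
   + ½·log gamma − ½·log A − ½·Σ w_i r_i² + b²/(2A)` with
   `A = gamma + Σ w_i x_i²`, `b = Σ w_i x_i r_i`.
2. **Laplace approximation over the rest.** The evidence integral over
   `(beta0, log sigma2, log alpha)` — log-transformed scale parameters
   so the optimization is unconstrained, with the
   `sigma2 → log sigma2` Jacobian included in the objective — is
   approximated as `g(mode) + d/2·log 2π − ½·log det(−H)` at the joint
   mode, `d = 3` (alternative) or `2` (null, `log alpha` fixed at 0).

Because the flat `beta0` prior is improper, each `log_marginal` is
defined only up to a shared constant; only the *difference* (the BF) is
calibrated, and no standalone marginal likelihood from this package
should be interpreted as such.

**Optimization.** BFGS on the negative kernel with the analytic
gradient, gradient tolerance 1e-8, at most 200 iterations, started at
the OLS intercept, the log OLS residual variance and `log alpha = 0`,
with up to three deterministic restarts from fixed perturbed starts.
A fit is reported `converged` when the gradient max-norm at the mode
is at most 1e-5 and the negative Hessian is positive definite. The
Hessian is computed by central finite differences of the analytic
gradient with step `1e-4 · max(1, |theta_j|)`. Everything is
deterministic: repeated calls on the same data give bit-identical
Bayes factors. Non-converged fits are flagged, scored as zero evidence
in benchmarks, and excluded from FDR calibration by default.

The test suite validates the Laplace evidence against an independent
dense-quadrature oracle (mode-centered, curvature-scaled Simpson
integration, itself checked against scipy's nested adaptive
quadrature); agreement is required to 0.1 log10 units over twenty
datasets spanning the simulation grid.

**Interpreting magnitudes.** With the diffuse Cauchy(0, 5) prior the
Occam penalty for the extra parameter is roughly 2–3 nats, so single
tests at modest effects (|log alpha| ≈ 0.2, n ≤ 1000) typically have
*negative* log10 BF even under the alternative; discrimination comes
from the BF being systematically larger than under the matched
permutation null. Significance should therefore always be assessed
through the permutation FDR calibration rather than a fixed BF cutoff.

## Comparison tests

All five comparison tests return the same `TestResult` contract and
the common score scale "larger = more significant" (−log10 p; log10 BF
for BTH).

- **Levene / Brown-Forsythe** (categorical covariates only): with
  absolute deviations `z_ts = |w_t(s) − center(w_t)|` from the group
  mean (Levene) or median (Brown-Forsythe),
  `W = (n−k)·Σ_t n_t (z̄_t − z̄)² / [(k−1)·Σ_t Σ_s (z_ts − z̄_t)²]`,
  referred to F(k−1, n−k). The group-size weights `n_t` in the
  numerator are essential for calibration under the unbalanced group
  sizes genotypes produce. Continuous covariates are refused rather
  than silently rounded; an explicit `round_dosage` utility exists for
  idealized-imputation experiments (rounding real dosage data discards
  imputation uncertainty and is discouraged).
- **Bartlett**: the classical pooled-variance chi-square, included as
  the normality-sensitive baseline. A zero-variance group raises a
  numerical-failure error.
- **CLS**: least-squares fit of `y ~ 1 + x`, then Spearman rank
  correlation (average ranks for ties) between squared residuals and
  `x`; p-value from the t approximation on n−2 df, or an exact
  permutation enumeration for n < 10.
- **dglm**: alternating estimation — weighted least squares for the
  mean with weights equal to reciprocal fitted dispersions, then a
  gamma GLM with log link for the dispersion with response = squared
  mean-model residuals, linear predictor `lambda0 + lambda1·x` and
  prior weights 1/2 (squared Gaussian residuals are
  `phi_i · chi²_1`, a gamma with shape 1/2). With a log link and
  constant prior weights the IRLS weights are constant, so each
  dispersion update is a single OLS solve of the working response;
  the alternation stops when the fitted Gaussian log-likelihood
  changes by less than 1e-8 (at most 50 iterations). The statistic is
  the 1-df likelihood-ratio chi-square against the constant-dispersion
  submodel. Non-convergence (more frequent at low MAF, as expected
  from the method's reliance on iteratively reweighted fits) is
  reported, not raised.

Degenerate inputs follow fixed conventions so that downstream FDR
machinery never sees missing values: fully tied deviations or squared
residuals (including perfect mean fits) give statistic 0 with p = 1.

## Permutations and FDR

The permutation null must destroy variance effects while preserving
mean effects, otherwise mean-effect traits would inflate the null.
`mean_preserving_permutation` fits `y ~ 1 + x` by least squares
(ordinary least squares; no error covariance structure is modelled),
permutes the residuals uniformly at random, verifies by a two-sided
slope t-test that the permuted residuals carry no mean effect
(p ≥ 0.10, redrawing up to 100 times, then accepting with a warning
flag), and returns fitted values plus permuted residuals. The residual
multiset — hence the residual mean — is preserved exactly.

FDR at threshold `t` is estimated as
`#{score_perm > t} / #{score > t}`, defined as 0 when nothing is
discovered. Signed scores (Bayes factors) are compared in absolute
value; p-value methods enter as −log10 p. The calibrated threshold is
the smallest candidate (scanning the union of observed real and
permutation score values) whose estimated FDR is at or below the
nominal level; if none qualifies the threshold is +infinity with zero
discoveries. One permutation per real test is the default, matching
the single-permutation design the estimator is built for; the count is
configurable. MAF-stratified calibration applies the same procedure
independently within bins with default edges
[0.05, 0.1), [0.1, 0.2), [0.2, 0.3), [0.3, 0.5]; both global and
stratified reports are produced rather than intersected, since either
may be the appropriate significance gate depending on the MAF profile
of the panel. Permutation-based FDR estimates are conservative by
construction (the permuted scores stand in for *all* nulls, not just
the undiscovered ones); the validation suite checks that the realized
false-discovery proportion at a nominal 0.05 stays below 0.10.
Benjamini-Hochberg is available for p-value methods as a labeled
convenience only.

## Simulation generators

Covariates: discrete genotypes are `Binomial(2, pi_maf)` minor-allele
counts; imputed dosages draw a latent genotype and then
`|c0|`, `c1`, or `2 − |c2|` with `c0, c2 ~ Normal(0, var 0.5)` and
`c1 ~ Normal(1, var 0.5)` — the second parameter is read as a
**variance** (sd = √0.5 ≈ 0.707), and out-of-range draws are clipped
to [0, 2] with a debug-level count (the mixture's central component is
unbounded, so a boundary convention is required; clipping keeps the
dosage interpretation). Binary covariates are Bernoulli(pi_maf)
indicators; generic continuous covariates are Uniform(0, 2).

Trait families:

- **ideal**: the BTH generating model itself, default sigma2 = 1.
- **additive_variance**: `Normal(beta0 + beta·x, sigma2 + a·x)` with
  additive coefficient `a` (null at 0) stored in the `log_alpha` slot.
- **log_gaussian**: exponentiated ideal draws — mean and variance
  coupled, as in raw microarray intensities.
- **gamma**: `Gamma(shape = mu_i, scale = 1)` with
  `mu_i = 1/(beta0 + beta·x_i)`, i.e. mean = variance = `mu_i` — a
  continuous analogue of overdispersed Poisson counts such as
  RNA-seq-derived abundances. This parameterization is what makes the
  mean-centered square-root transform (below) the appropriate variance
  stabilizer; a shape-1/scale-`mu` reading would leave
  `Var(sqrt Y) ∝ mu` and no square-root transform could decouple mean
  and variance. Default weak-null coefficients `beta0 = 0.1`,
  `beta = 0.05` put trait means at 5–10 (expression-count scale,
  shapes ≥ 5, approximately symmetric densities); shapes below 1 would
  be J-shaped with mode at zero, which is not a plausible expression
  trait and sits outside the stabilizer's regime.
- **bimodal**: with probability `lambda_mix` (default 0.4) a
  Normal(10, 1) draw, otherwise an ideal draw — the signature of an
  epistatic interaction producing a second mode.

The packaged default grid is n ∈ {300, 500, 1000},
pi_maf ∈ {0.05, 0.2, 0.3}, beta ∈ {0, 0.2, 0.5, 1},
log alpha ∈ {−0.2, −0.1, 0, 0.1, 0.2}, beta0 ∈ {0, 1}, sigma2 = 1.
Benchmark suites pair every replicate with one mean-effect-preserving
permutation null; random streams derive from one master seed via seed
sequences keyed by (config, replicate) counters, so suites are
bit-reproducible regardless of execution order.

What the generators do **not** emulate: linkage disequilibrium,
multi-locus architecture, relatedness/population structure, batch
effects, or missingness. Each covariate is independent. Passing tests
on these simulations therefore demonstrate calibration and power under
the stated trait models, not robustness to structured confounding in
real cohorts — on real data the preprocessing pipeline (PC control,
residualization) is the intended complement.

## Trait-distribution classifier and transformations

A trait sample is summarized by one-sided Kolmogorov-Smirnov
statistics `D+ = sup_x [ECDF_query(x) − ECDF_ref(x)]` (the "query
above reference" side; one of the two possible one-sided conventions,
fixed here) against 79 reference densities sampled with location and
scale matched to the query's first two moments (exact by construction,
using each family's analytic mean and variance). The default bank
spans Gaussian, Student-t (11 df values), Laplace, uniform, logistic,
Gumbel, exponential, lognormal (6 shapes), gamma (11 shapes), beta
(10 shape pairs), Weibull (5), Pareto (5), and 25 two-component
Gaussian mixtures over a weight × separation grid. The bank is
configurable; the classifier contract depends on its size and the
moment matching, not the exact list, and the identifier list is
embedded in saved model artifacts so bank/model mismatches are
detected at load time.

Training data: 7 generating models × 4 effect cells
((log alpha, beta) zero/nonzero combinations) × 50 samples, discrete
genotypes at MAF 0.2, n = 200, reference sample size 100. Two of the
seven classes have no counterpart among the benchmark families and are
defined here by convention: *exponential mean* (Gaussian noise around
`exp(beta0 + beta·x)`) and *exponential residual* (linear mean with
mean-zero shifted-exponential noise whose scale follows the
multiplicative heteroskedasticity). A random forest (300 trees) is
fit on the feature vectors; per-class precision/recall and macro
accuracy come from stratified 5-fold cross-validation. Features are
computed on the pooled trait vector by default; a per-genotype-group
feature block is available as an option. Cross-validated macro
accuracy on the default training set is required to beat three times
chance (3/7); bimodal and log-Gaussian separate almost perfectly,
while the ideal and additive-variance classes (both Gaussian at these
effect sizes) are intrinsically confusable — a known limitation that
matters little in practice because neither label triggers a
transformation.

Prescriptions: label log_gaussian → natural log transform (strictly
positive traits); label gamma → mean-centered square root (non-negative
traits; the subtracted mean of the square roots is recorded); all
other labels → none. The point of the transformations is the weak
null: mean effects without variance effects must *not* be reported as
variance effects, and the validation suite checks that the spurious
pre-transform signal disappears (PR-AUC returns to ≈ 0.5) after the
prescribed transform.

## Benchmarking

Precision-recall curves are computed over descending score thresholds
with tied scores grouped at a single threshold (no arbitrary intra-tie
ordering), AUC by trapezoidal integration over recall, and average
precision as the recall-increment-weighted mean of precision. The
curve starts at (recall 0, precision of the top tie group), so an
uninformative constant scoring over a balanced suite yields AUC 0.5.
Datasets are labeled real-vs-permutation: under an alternative
configuration this measures power against the matched null; under a
null configuration AUC ≈ 0.5 certifies that the permutation generates
a true null. A truth-based labeling (requiring a nonzero simulated
variance effect) is available. Non-converged fits score 0 rather than
being dropped, so all methods face identical label sets; convergence
counts are reported alongside. Method comparisons report AUC and
average-precision differences with 1000-draw bootstrap percentile
intervals over datasets.

## Preprocessing and I/O conventions

- Coordinates are 1-based inclusive; variant-to-feature distance is 0
  inside the feature interval and the distance to the nearest edge
  otherwise; cis pairs satisfy distance ≤ window (boundary inclusive).
- The genotype interchange format is TSV (features × samples), not
  VCF: variance-effect scans start from dosage/genotype matrices, and
  a VCF importer would add scope without exercising any method here.
  `bcftools query -f '%ID[\t%DS]\n'` (or `[\t%GT]` recoded 0/1/2)
  produces the expected layout from a VCF.
- MAF is `min(m, 1−m)` with `m` = row mean / 2 for discrete or dosage
  rows; supplied MAF columns take precedence.
- Missing trait or covariate values drop samples pairwise per test,
  with the retained n logged.
- Expression pipeline order: log₂; genotype PCs (SVD of the centered
  variants × samples matrix); per-gene least-squares residualization
  on known covariates plus genotype PCs (mean-centered residuals,
  collinear design columns dropped with a warning); expression PCs of
  the residual matrix and a second residualization. Genotype PCs enter
  before expression PCs by convention, since the former capture
  ancestry that should not leak into the latent-factor estimate.
- Quantile normalization maps each feature row to
  `Phi^{-1}((rank − 0.5)/n)` with average ranks for ties; tie-free
  rows then share their sorted value multiset exactly and have mean
  within numerical zero of 0. Constant rows map to zeros with a
  warning.

## Problem sizes in the validation suite

The shipped validation suite runs the Laplace-vs-quadrature comparison
on 20 datasets of n ≤ 50; null calibration on 500 replicates at
n = 300; the headline method comparison on 300 replicates (plus
matched permutation nulls) at n = 1000; power ordering, monotonicity
and transformation efficacy on 300 replicates per configuration at
n = 300–1000; FDR conservativeness on a 500 + 500 suite at n = 500;
parameter recovery on 100 replicates at n = 1000; and classifier
cross-validation on the full 1400-sample training set. These sizes
give Monte-Carlo error comfortably inside each asserted tolerance
while keeping the whole suite at a few minutes on one CPU.

## Known limitations

- One covariate per test; no joint multi-covariate variance model.
- The Laplace approximation assumes a unimodal, roughly Gaussian
  posterior kernel; heavy misspecification (e.g. extreme bimodality)
  can degrade the evidence estimate — the classifier is the intended
  guard.
- Permutation FDR is conservative; with few tests the threshold grid
  is coarse and discovery counts are step-like.
- The exponential-mean and exponential-residual classifier classes are
  package conventions (their literature definitions are not fully
  specified), and the 79-density bank is a representative default
  rather than a canonical list.
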