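# Methods

## The model

`geoadd` estimates geographic variation in a binary health outcome — here
combined overweight/obesity (BMI ≥ 25) versus normal weight (18.5 ≤ BMI < 25)
among women of reproductive age — while adjusting for individual-level risk
factors. The core is a Bayesian geo-additive (structured additive) logistic
regression: for woman *i* living in region *s(i)*,

    y_i ~ Bernoulli(expit(eta_i))
    eta_i = x_i' beta + f_age(a_i) + f_page(p_i) + u_{s(i)} + v_{s(i)}

with

- **beta** — fixed effects of dummy-coded categorical covariates (education
  of respondent and partner, urban/rural residence, religion, wealth
  quintile, ethnicity), diffuse Gaussian priors N(0, 1e6);
- **f_age, f_page** — smooth functions of respondent and partner age,
  modelled as penalized cubic B-splines (P-splines): K = 20 basis functions
  on equidistant knots over the observed range, coefficients shrunk by a
  second-order random-walk (RW2) prior with variance tau2_f, which shrinks
  toward linear functions;
- **u** — structured spatial effects with an intrinsic CAR (ICAR) prior:
  precision (1/tau2_spat)·Q with Q = degree − adjacency of the region graph,
  penalizing differences between neighbouring regions;
- **v** — unstructured iid N(0, tau2_unstr) region effects capturing
  non-spatial heterogeneity; u + v is the "total" region effect that the
  maps summarize;
- inverse-gamma IG(a, b) hyperpriors, a = b = 0.001, on every variance.

Region graphs are plain-text neighbour lists. The shipped Nigeria fixture
holds the 37-state adjacency (hand-built from public state geography) and is
merged at graph construction into the 31 analysis regions (the pre-1996 30
states plus Abuja; the 1996 splits Bauchi/Gombe, Ondo/Ekiti,
Nassarawa/Plateau, Rivers/Bayelsa, Sokoto/Zamfara and Enugu/Ebonyi are
re-merged), which is the aggregation at which state-level tables for the
2008 Nigeria DHS are reported.

## Inference: Pólya-Gamma Gibbs sampling

Augmenting each observation with omega_i ~ PG(1, eta_i) renders every
coefficient block conditionally Gaussian (precision B'ΩB + prior precision,
mean given by the corresponding normal equations with working response
kappa = y − 1/2), so the sampler is an exact, tuning-free Gibbs scheme:

1. draw omega | eta elementwise from PG(1, eta_i);
2. draw each Gaussian block (beta; each spline block; u jointly; v) from its
   full conditional;
3. draw each variance from IG(a + rank/2, b + quadratic form/2), where rank
   is K − 2 for an RW2 block, R − (number of graph components) for the ICAR
   block and R for the unstructured block;
4. re-center each spline block to mean zero over the observed covariate
   values and the ICAR block to mean zero within each graph component,
   transferring the removed constant into the intercept.

The PG(1, z) draws use an exact Devroye-type alternating-series rejection
sampler (`geoadd._polyagamma`), vectorized over observations; it is validated
against the closed-form PG mean/variance and Laplace transform, and the whole
sampler against an independent quadrature oracle (below).

Centering details: because the B-spline basis is a partition of unity,
subtracting a constant from a block's coefficients shifts its fitted function
by exactly that constant, so the re-centering in step 4 is an exact
reparameterization that leaves eta unchanged. For the ICAR block this is
likewise exact on a connected graph (all shipped graphs and lattices are
connected); on a disconnected graph the per-component constants beyond their
observation-weighted mean act as an additional identification constraint.
The unstructured block has a proper prior and is not centered.

Defaults: 12,000 iterations, 2,000 burn-in, thinning 10 (conventions of the
BayesX family of samplers for this model class). Variances are initialized
at 0.1; coefficients at 0. All draws are bit-reproducible given the seed
(one `numpy.random.Generator` drives the whole chain).

Chain health on the recovery fixture is checked via effective sample size
(Geyer initial-positive-sequence estimator; intercept ESS > 100) and Geweke
z-scores (|z| < 3 for ≥ 95% of parameters). The Geweke diagnostic is
implemented in-package; ESS is cross-checked against `arviz.ess` in tests.

## Marginal model

For the conventional table presentation the package also fits a standard
maximum-likelihood logistic regression with age grouped (respondent ≤ 25 /
26–35 / 36–49; partner ≤ 30 / 31–40 / 41+) and Wald 95% CIs, via IRLS with
step-halving (deviance is non-increasing by construction; quasi-complete
separation flagged at |coef| > 15). The IRLS fit is cross-checked against
statsmodels GLM in the test suite.

## Posterior summaries

- POR = exp(posterior mean of the log-odds effect); equal-tailed quantile
  credible regions, exponentiated. (`mean_of_exp=True` gives the
  E[exp(effect)] alternative.) Tables print two decimals, e.g.
  "1.24 (1.14, 1.36)".
- Nonlinear curves: pointwise posterior mean of the centered smooth with an
  80% equal-tailed band by default.
- Maps: the total region effect u + v per draw; a region is "positive" if
  the lower bound of its nominal-level CR exceeds 0, "negative" if the upper
  bound is below 0, else "none". Default nominal level 80% (95% available
  via the level argument). Exported GeoJSON features gain por, cr_low,
  cr_high, category and fill colours (red/green for POR, black/grey/white
  for categories).

## Synthetic data

Real DHS microdata are restricted-access, so the generator emulates the
survey at the record level with known ground truth: covariates are drawn
independently from NDHS-2008-like marginal shares, respondent age from a
rounded truncated normal (mean 29.3, SD 7.1 on [15, 49]), partner age
likewise (40.9, 12.8 on [15, 95]); regions uniformly unless weighted. The
default fixed effects are the published adjusted odds ratios for education,
partner education, residence, religion and wealth; the default smooths are
0.9·sin(pi(a−15)/60) (peak at age 45) and 0.5·sin(pi(a−15)/110) (peak at
70), centered over their integer age grids; structured effects are exact
ICAR draws (spectral construction, covariance tau2·Q+, per-component
sum-to-zero), default tau2_spat = 0.5 with iid unstructured effects of
variance 0.05. When no intercept is given it is calibrated so the expected
outcome probability is near the published overall prevalence of 20.9%. A
12% underweight stratum (BMI uniform on [15, 18.5)) exercises the exclusion
step; otherwise BMI is drawn uniformly inside the destination WHO band
([18.5, 25) or [25, 35)) so categorization is exactly invertible.

What the generator does **not** emulate: joint covariate dependence (e.g.
wealth–education correlation), household/cluster sampling structure, survey
weights, or a realistic continuous BMI distribution. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model, not robustness to the design features of real DHS data.

## Preprocessing conventions

WHO BMI bands are half-open on the right: underweight < 18.5, normal
[18.5, 25), overweight [25, 30), obese ≥ 30 (printed upper bounds like
"24.9" are display rounding). Exclusion order is underweight first, then
complete-case on the model covariates, so the underweight count is
reproducible regardless of the missingness pattern; the ledger reconciles
retained + excluded to the input count exactly. No biological-plausibility
filter on BMI is applied by default.

## Numerical choices

- IRLS convergence at |Δdeviance| < 1e-8, at most 100 iterations.
- Gaussian block draws by dense Cholesky (block sizes ≤ ~40 here).
- B-spline evaluation nudges the closed right endpoint into the last knot
  interval by a relative 1e-9 so the basis sums to one on the full closed
  range.
- Chi-square tests are Pearson without continuity correction; Mann-Whitney
  switches from exact enumeration to the tie-corrected normal approximation
  at min(n) > 8 or in the presence of ties; crude ORs use Woolf (log-Wald)
  intervals, with an optional 0.5 continuity correction for zero cells.
- Desk-scale problem sizes used in the shipped checks: the recovery study
  uses a 6×6 lattice with n = 10,000 and a single chain of 2,500 iterations
  (500 burn-in, thin 4); CR-coverage uses 50 replicates of n = 800 with 700
  iterations each. These sizes were chosen once as sufficient for the
  stochastic tolerances involved.

## Known limitations

- Single-chain inference; no multi-chain R-hat.
- The marginal and geo-additive fits use complete cases only; partner
  variables of unpartnered women are an explicit "missing" level in
  descriptives but drop records from model fits.
- The Nigeria adjacency is hand-constructed from public maps at state
  resolution; tiny boundary disagreements do not affect the merged
  31-region topology's connectivity but could flip individual adjacencies.
- The published posterior tables for the real survey are not reproducible
  here because the underlying microdata are restricted; the pipeline's
  correctness is instead established against oracles and simulations with
  known truth.
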