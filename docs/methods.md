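# Methods

`tsopgs` implements a genetically informed decomposition of substance-use
liability: polygenic scores (PGSs) built from GWAS summary statistics are
regressed on the latent factors of a trait-state-occasion (TSO)
structural equation model of four substance-use scores (cigarettes,
alcohol, cannabis, other illicit substances) measured at three ages.
This note records the model, the estimation machinery, the synthetic-data
generator that stands in for restricted cohort data, and the numerical
and design choices that were genuinely open.

## The trait-state-occasion model

Let `y_{k,t}` be the bounded score of substance `k` (k = 1..4) at
occasion `t` (t = 1..3), stacked substance-major into a 12-vector `y`.
The measurement model is

    y_{k,t} = nu_{k,t} + lambda^C_{k,t} C + lambda^S_{k,t} S_k + O_t + eps_{k,t}

with a common liability factor `C` loading on all 12 indicators, a
specific factor `S_k` per substance loading on its three repeated
measures, and an occasion factor `O_t` per wave loading with a *fixed*
unit coefficient on the four same-wave indicators.  All factor variances
are fixed to 1, all factors are mutually uncorrelated, residual
variances `theta_{k,t}` and intercepts are free.  The free
covariance-structure parameters are therefore 12 common loadings, 12
specific loadings and 12 residual variances — 36 against the
12·13/2 = 78 unique covariance elements, so the baseline model has 42
degrees of freedom.  This constraint set (no occasion autoregression,
occasion loadings and variances fixed) is the unique member of the
classic TSO family consistent with that df count, and it is what
`build_spec(4, 3)` constructs.

The identification rules generalise: the common factor (and the
occasion factors) exist only when there are at least two substances; a
single-substance, three-occasion model reduces to one specific factor
with three loadings and three residuals (saturated, df = 0).

### Structural (MIMIC) block

Observed exogenous predictors `x` (PGSs, sex, principal components) may
be regressed onto any trait factor: `eta = B x + zeta` with
`var(zeta) = 1` fixed.  Predictors are treated as fixed regressors
(conditional likelihood), mirroring the default of mainstream SEM
software: the row-wise conditional mean is `nu + Lambda_t B x_i` and the
conditional covariance `Lambda Lambda' + Theta` does not involve `B`.
Marginally the factor variance grows to `1 + b' S_x b` (`S_x` the sample
predictor covariance) and factors sharing predictors become correlated
through `B S_x B'`; the marginal implied moments used for fit indices
and standardisation account for this.

The *fully standardised* solution rescales every coefficient by the
model-implied standard deviations of its source and target; for a
structural coefficient, `b_std = b · sd(x) / sd(eta)`.  Because both the
predictor and the factor are standardised, `b_std` is the model-scale
correlation-like effect and `b_std^2` is the share of factor variance
the predictor explains on its own.  Delta-method standard errors
propagate the (robust) parameter covariance through a numerical Jacobian
of the standardisation map.

An identification caveat worth recording: `B` enters only the mean
structure, so its columns are resolved through `Lambda_t`.  If the
common-factor loading vector were exactly proportional to the sum of the
specific-factor loading vectors (as happens when all loadings are
equal), the common-factor coefficient would be indistinguishable from a
uniform shift of the specific-factor coefficients.  Real loadings vary
across indicators; the synthetic generator's defaults vary accordingly.

## Estimation

**FIML.** Rows with at least one observed indicator contribute the
log-density of their observed sub-vector.  Rows are grouped by
missingness pattern; patterns with the same number of observed variables
are processed as one stacked linear-algebra batch, and all data enter
through per-pattern cross-product matrices, so one likelihood-plus-
gradient evaluation costs O(#patterns · p³) regardless of n.  The
gradient is fully analytic (adjoints with respect to the conditional
covariance and the mean-coefficient matrix, chained onto loadings,
residual variances, intercepts and structural coefficients).

**Optimisation.** Quasi-Newton (L-BFGS-B) on a transformed space (log
residual variances) from one deterministic start — loadings at half the
indicator SD, residual variances at half the indicator variance,
intercepts at the observed means, structural coefficients at zero —
followed by Newton polishing with a finite-difference Hessian of the
analytic gradient.  Convergence requires the maximum component of the
per-observation average score, max|grad|/n, to fall below 1e-5; on
failure up to five seeded jittered restarts are attempted before a
`ConvergenceError` (carrying the best parameters) is raised.  The sign
indeterminacy of each factor is resolved by making its loading sum
positive.  Residual variances below 1e-6 set a Heywood warning flag.

**Standard errors.** The observed information `A` is the negative
finite-difference Hessian of the analytic gradient at the optimum; the
meat `B` is the sum of outer products of analytic casewise scores.
Naive SEs are `sqrt(diag(A^-1))`; robust (sandwich) SEs are
`sqrt(diag(A^-1 B A^-1))`.  Robust SEs are the default basis for Wald
tests and confidence intervals because the substance-use scores are
bounded counts, not normal deviates.  Note that under iid non-normal
*residuals* the information equality still holds asymptotically for
mean-structure coefficients; the sandwich matters most for loading and
variance parameters and under heteroscedasticity.

**Saturated and baseline models.** The saturated mean/covariance under
missingness is estimated by EM (same pattern-batched sufficient
statistics; converged at relative log-likelihood change < 1e-8; closed
form on complete data).  The independence baseline factorises over
variables, so its FIML optimum is available in closed form from
per-variable observed-data moments.

**Fit indices.**  `T = 2(ll_sat − ll_model)` with the model evaluated at
its marginal implied moments;
`CFI = 1 − max(T−df, 0)/max(T_b−df_b, T−df, 0)`;
`RMSEA = sqrt(max(T−df, 0)/(df·n))` (n, not n−1, in the denominator —
configurable in principle, negligible at study sizes); `SRMR` is the
root-mean-square of correlation-metric residuals against the
EM-saturated moments over the lower triangle including the diagonal.
With df = 0 the CFI and RMSEA are reported as undefined with a reason.
The scaled (Satorra-Bentler-type) test statistic is deliberately out of
scope: robust standard errors are provided, the unscaled T is reported.

**Variance decomposition.** For the baseline model the implied indicator
variance is exactly `lambda_C² + lambda_S² + 1 + theta`; the four shares
are reported per indicator with their across-indicator averages.  The
identity "shares sum to one" is structural, and is verified to 1e-8 on
every fitted model in the test suite.

## Polygenic scores

Summary statistics are harmonised to the genotype panel: SNPs absent
from the panel are dropped, rows whose effect allele matches the panel's
alternate allele have the beta sign flipped and alleles swapped, and
strand-ambiguous SNPs (A/T, C/G) are dropped rather than
frequency-matched.  Clumping is the greedy rule: visit SNPs in ascending
p-value order (ties broken by position, then id); each index SNP removes
all unvisited same-chromosome SNPs within the physical window whose
dosage r² with it exceeds the threshold.  Defaults: r² > 0.10 within a
250 kb window — the source protocol prints a "250-bp" window, which is
treated as a kilobase typo since a 250-bp clumping window is vacuous at
GWAS SNP spacing; both values are configurable.  Scores are the sum of
effect sizes times effect-allele dosages over retained SNPs with
p ≤ 1 (a single inclusive threshold; no threshold scan), missing
dosages contribute the SNP's mean dosage, and every score is
standardised to mean 0, variance 1 (n−1 denominator).

## Association stages

*Single-PGS models*: one TSO fit per score in which the common and all
four specific factors are simultaneously regressed on that score plus
covariates (sex and ten principal components).  Simultaneous regression
keeps the factor decomposition intact while measuring each factor's
association.  Wald p-values use robust SEs on the raw coefficient;
95% CIs are reported on the standardised scale.  Benjamini-Hochberg
adjustment is applied per factor across scores (five families) by
default; a single global family is available behind a switch since the
source protocol does not pin the family down.

*Multi-PGS models*: per factor, the FDR-surviving scores are entered
jointly — split into a substance-use set (A) and a trait/vulnerability
set (B) by a declared category map — with the other trait factors
regressed on covariates only.  A design condition number above 1e8
raises a collinearity error naming the most correlated pair.
Non-converged fits are flagged and excluded from the FDR family with a
warning rather than poisoning the family.

## Synthetic data

The generator emulates the statistical features the analysis relies on,
with defaults chosen once as the study conditions:

- **Genotypes** — biallelic dosages in Hardy-Weinberg proportions at
  allele frequencies drawn uniformly from (0.05, 0.5].  Haplotypes
  within an LD block follow a first-order autoregressive
  Gaussian-threshold copula (default block size 10, latent correlation
  0.6), giving tunable adjacent-SNP r² for clumping tests; blocks are
  independent, spaced 1 kb within and >250 kb between blocks so a block
  sits inside the clumping window and distinct blocks sit outside it.
- **Summary statistics** — reported beta = true beta + N(0, se²) with
  se = 1/sqrt(N·2f(1−f)) for discovery sample size N (default 50 000,
  infinity = noise-free limit); two-sided Wald p-values; 5% of rows have
  alleles swapped (sign flipped) to exercise harmonisation, and 5% of
  panel SNPs are strand-ambiguous to exercise dropping.
- **Phenotypes** — the TSO structure above with unit-variance factors.
  Structural effects enter the factor as `sum_j b_j PGS_j + b_sex sex`
  with the residual scaled so the marginal factor variance is 1; a
  configuration implying explained variance above 1 is rejected.
  Default loadings vary across indicators and average to the variance
  decomposition a common-liability analysis of this kind reports
  (22% common, 34% specific, ~19% occasion, ~25% residual):
  lam_common ≈ 0.8–1.3, lam_specific ≈ 1.1–1.5, residual SD 1.15.
  Continuous indicators are mapped to bounded counts (FTND 0–10, AUDIT
  0–40, CAST 0–24, illicit count 0–15) by rank-preserving quantile
  discretisation onto a truncated negative binomial (r = 1.2, mean 15%
  of the ceiling) — right-skewed, mimicking screening-instrument totals,
  and order-preserving so the latent correlation structure survives
  approximately.  The marginals are a stand-in, not a calibration: no
  published score distribution is being matched.
- **Covariates** — sex ~ Bernoulli(0.5); ten principal components as
  standard normals.  The pipeline only needs covariates with the right
  role; realistic population stratification is out of scope.
- **Missingness** — MCAR per-cell at a configurable rate (default 10%),
  or MAR with logistic dependence on a covariate whose intercept is
  solved so the marginal rate matches the request.  Rows losing all 12
  indicators are dropped and counted; covariates are never blanked.

Every study carries a truth record (latent factor values, true PGSs,
loadings, structural coefficients, seed) for recovery testing.  What
passing tests show: the estimator is unbiased with calibrated robust
intervals *under the generator's latent-normal, rank-discretised world*.
What they do not show: robustness to real-data features the generator
omits — genuine LD maps and stratification, floor effects stronger than
the negative-binomial tail, informative (MNAR) dropout, measurement
non-invariance across waves.

## Problem sizes and numerical tolerances

Verification studies use the sizes at which their Monte-Carlo error
supports the stated bands: parameter recovery and partialling use 50
replicates at n = 4000; chi-square calibration 200 replicates at
n = 4000; the null size of the robust Wald test 200 replicates of 18
scores at n = 1500 (18 000 tests); coverage under scaled-t(3) residuals
200 replicates at n = 800.  Exact identities (FIML vs row-wise
evaluation, BH vs its definition, clumping vs exhaustive brute force,
share sums) are asserted at 1e-8–1e-12.  Replicate-count bands (e.g.
95 ± 3% coverage) are compared on counts, not floats.

## Known limitations

- Categorical-indicator estimation (WLSMV-style) is not implemented;
  bounded counts are modelled as continuous with robust SEs, which
  attenuates standardised effects slightly relative to the latent scale.
- The sandwich meat involves fourth moments, so with heavily skewed
  bounded counts the robust Wald test can be somewhat conservative at
  realistic sample sizes even though it is asymptotically exact; size
  calibration is therefore verified under the correctly specified
  continuous condition.
- No scaled test statistics; T is compared to the nominal chi-square.
- Fit indices are defined for measurement-only models; for structural
  models the chi-square compares marginal implied moments against the
  unconditional saturated model, which folds predictor effects into the
  moments rather than conditioning on them.
- The variance decomposition requires the baseline (no-predictor) model,
  where the orthogonal decomposition is exact.
- PGS construction implements a single inclusive p-threshold; no
  high-resolution threshold scan or empirical p-values.
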