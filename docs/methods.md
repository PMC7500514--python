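# Methods

`lgctraj` analyses longitudinal regional brain-volume data with linear
latent growth-curve models.  This note documents the models, the synthetic
cohort that exercises them, the numerical choices, and the limitations.

## The growth model

For subject *i*, region *r*, occasion *j* at time-in-study $t_{ij}$ (years
since baseline) the percent-scaled volume is modelled as

$$
y_{irj} = \beta_0 + \beta_a a_i + \beta_{a^2} a_i^2 + \beta_v v_i
        + (\beta_s + \beta_{sa} a_i + \beta_{sv} v_i)\, t_{ij}
        + u_{0ir} + u_{1ir} t_{ij} + e_{irj},
$$

with $a_i$ the entry age centered at 65 years, $v_i$ the grand-mean
centered intracranial volume (ICV), $(u_{0ir}, u_{1ir}) \sim N(0, G_r)$
the random intercept and slope, and $e_{irj} \sim N(0, \sigma_r^2)$.
Separating entry age from time-in-study splits between-person age
differences (which carry cohort and selection effects) from genuine
within-person change: $\beta_s$ is the annual decline at age 65 and
$\beta_{sa}$ its acceleration per year of entry age.  The optional sex
extension adds male indicators on the level ($\text{sex}$,
$\text{sex}\times a$, $\text{sex}\times a^2$) and on the slope
($\text{sex}\times t$, $\text{sex}\times t\times a$); the sex test is the
2-df likelihood-ratio test of the two slope interactions.  Female is the
reference level (sex coded 0/1, uncentered).

**Estimation.** Maximum likelihood (not REML) is the default so that
likelihood-ratio tests of variance components and of nested fixed effects
are coherent on one scale.  The relative covariance $\Gamma = G/\sigma^2$
is parameterized by its Cholesky factor with log diagonal (unconstrained,
always PSD); for fixed $\Gamma$, $\beta$ has a GLS closed form and
$\sigma^2$ a closed form, leaving a 3-parameter (or 1-parameter, random
intercept only) profiled deviance optimized by L-BFGS-B from three
starting points (relative tolerance 1e-8).  All per-subject operations are
padded to the maximum occasion count and batched, so a cohort-scale fit
takes tens of milliseconds and deletion/bootstrap refits are affordable.
Subjects contribute all and only their observed waves (full-information
likelihood, valid when dropout is missing-at-random).

**Boundary LRT.** Removing the random slope removes its variance (a
boundary parameter) and the intercept–slope covariance, so the statistic
is referred to a 50:50 mixture of $\chi^2_1$ and $\chi^2_2$; a zero
statistic maps to p = 1.  Confidence intervals for fixed effects are Wald.

## Percent-of-intercept scaling

Each region is divided by its own model-implied population level at entry
age 65, mean ICV and baseline, times 100.  After scaling, $\beta_s$ reads
as percent of the age-65 volume lost per year, comparable across regions
of very different absolute size.  Rescaling an already-scaled cohort
refits an intercept of ~100 and is a near-no-op.

## Time binning

Latent growth modelling shares slope loadings across subjects, so the
slightly irregular observation times are collapsed to a small set of
representative values: an exact dynamic program computes the optimal
contiguous k-median partition of the sorted times (cluster value = the
cluster's weighted median; cost = total L1 deviation).  The default k is
the smallest whose cost falls below 1% of the single-cluster cost —
producing narrow bins without presuming any particular published bin
count.  Mixed-model fitting always keeps the exact times; only the
latent-growth (bivariate Bayesian) stage uses the binned loadings.

## Influence QC

Cook's distance per subject,
$D_i = (\hat\beta - \hat\beta_{(-i)})^\top \widehat{\mathrm{Cov}}(\hat\beta)^{-1} (\hat\beta - \hat\beta_{(-i)})/p$,
is computed from exact case-deletion refits (variance components
re-estimated, warm-started) or a cheaper one-step GLS update holding the
variance components fixed (flagged in the report; within a few percent of
exact for influential subjects).  The likelihood contribution is the
subject's marginal log-likelihood at the full-data estimate.  A subject is
excluded when $D_i > 0.5$ and $\ell_i < -7.5$, or $D_i > 1$ and
$\ell_i < -4$ — joint thresholds chosen by visual inspection in the
reference analysis, kept configurable because $\ell_i$ depends on the data
scale.  A deletion refit that fails marks the subject indeterminate rather
than silently passing it.  Note that in a random-slope model a single-wave
outlier is partly absorbed by the subject's random effects, so fabricated
waves show up reliably in $\ell_i$ and only more diffusely in $D_i$ —
which is exactly why the rule requires both.

## 20-year extrapolation and bootstrap

Expected loss from 65 to 85: five 4-year segments whose annual slope is
refreshed at ages 65, 69, 73, 77, 81, i.e.
$\mathrm{loss}_{20} = 20\beta_s + 160\beta_{sa}$ (percent of the age-65
volume; negative = loss).  Variability comes from a nonparametric
bootstrap that resamples whole subject trajectories (preserving
within-subject dependence), refits every region per replicate (warm
started), and reports percentile intervals.  For each ordered region pair
the "faster decline" mass is the fraction of replicates in which A's loss
magnitude exceeds B's; exact ties split 0.5/0.5, so mass(A,B) +
mass(B,A) = 1.  Percentile (not BCa) intervals are used; the interval type
was an open choice and percentile is the simplest defensible default.
Note the pairwise mass is a *within-dataset* posterior-like quantity: for
two regions with identical generating parameters its expectation over
datasets is 0.5, but any single dataset yields a value spread roughly
uniformly — only literally identical data give 0.5 exactly (all ties).

## Bivariate Bayesian growth model

For a region pair, the 4-vector of latent intercepts and slopes
$(i_A, s_A, i_B, s_B)$ is jointly normal with covariance $\Psi$, and the
two same-occasion residuals share a 2×2 covariance $\Sigma_e$ (constant
across occasions).  Covariates (entry age, age², ICV, sex) act on both
intercepts and slopes.  The quantity of interest is the slope–slope
("change–change") correlation
$\rho_{ss} = \Psi_{s_As_B}/\sqrt{\Psi_{s_As_A}\Psi_{s_Bs_B}}$: whether
fast decliners in one region decline fast in the other.

**Priors and sampling.**  Fixed effects $\sim N(0, 10^{10})$; covariance
matrices of size p carry the improper Inverse-Wishart(0, −p−1) — uniform
over covariance elements, the convention of common SEM software.  All full
conditionals are then conjugate: per-subject latent 4-vectors and fixed
effects are Gaussian, $\Psi \mid b \sim \mathrm{IW}(\sum b_ib_i^\top,\,
n-p-1)$ and similarly for $\Sigma_e$.  The Gibbs sampler is batched with
numpy across subjects (~1.5 ms per iteration at n = 300).  Defaults: 2
chains × 20 000 iterations, half burn-in (tests and the default pipeline
use shorter, stated runs); convergence requires split-R̂ < 1.05 on
$\rho_{ss}$, the slope variances and covariance, and the residual
correlation.  If the improper prior degenerates (non-PD or vanishing
variance draws), the fit automatically reruns under a documented proper
fallback IW(εI, p+1), ε = 1e-4, and is flagged — never silent.

**Plausible values.**  Each retained draw of a subject's latent slope
(covariate part plus random effect) is a plausible value; the per-subject
posterior mean and SD summarize it.  Subjects observed only at baseline
retain essentially the marginal slope SD — uncertainty is propagated, not
imputed away.  The posterior mass of $\rho_{ss}$ on the minority side of
zero, m, is graded \* (m < 0.05), \*\* (m < 0.005), \*\*\* (m < 0.0005).

## Slope matrix and PCA

One slope per subject and region is the mean, over all bivariate fits
containing the region, of that fit's plausible-value means (the
"mean of means").  This estimator is deliberately simple and known to be
attenuated by shrinkage — correlations among the resulting columns are
smaller in magnitude than the bivariate posteriors but keep their sign
pattern, which is what the PCA consumes.  Columns are residualized on
{1, ICV, sex, entry age} (entry age enters linearly; the quadratic term is
not part of this adjustment), then the covariance matrix (not correlation
— columns are already on a common %/yr scale) is eigendecomposed.
Components are ordered by eigenvalue and signed so the largest-magnitude
loading is positive; by default components up to 85% cumulative variance
are reported.

## Synthetic cohort

The generator emulates a single-site healthy-aging panel: 231 subjects,
entry age truncated-normal on [64, 87] with mean 70.8 (SD 5 — the source
design reports only mean and range, so the SD is a fixed package choice),
49% female, ICV ~ N(1.45·10⁶, 1.3·10⁵) mm³ with a modest male–female
offset so ICV absorbs sex differences in volume; planned waves at 0, 1, 2,
4 years with half-normal positive timing jitter (SD 0.08 yr, reproducing
realized bins slightly above the planned values) and an extra wave near 3
years for a 10% minority.  Volumes are generated on the percent scale
(fixed effects as in the model above; cross-region random slopes drawn
under a specified correlation matrix R; within-region intercept–slope
coupling by a configurable correlation) and multiplied back to mm³ by each
region's age-65 volume, so the scaling stage has real work to do.
Defaults: random intercept SD 6%, residual SD 1%/occasion, slope
parameters available as presets from the packaged reference table.

Dropout is a per-wave logistic hazard on the standardized last-observed
mean volume (coefficient −0.5) and standardized entry age (+0.5) —
missing-at-random by construction, monotone (once missing, always
missing) — with the hazard intercept calibrated numerically (Brent root
finding on the expected survival using baseline volumes) so final-wave
retention hits the design target, 72% by default.  The extra 3-year wave
rides along until the subject's first missed planned wave.

**What the generator does not emulate:** segmentation and motion
artifacts (the residual is homoscedastic Gaussian; real scan noise is
heavier-tailed and occasionally systematic), scanner drift, cohort
effects, non-linear true trajectories, practice/attrition interplay
beyond the single MAR hazard, and left/right hemisphere structure
(regions are bilateral sums).  Passing tests therefore demonstrate that
the estimators recover the truth under the model's own assumptions at the
study's design size — not that those assumptions hold for any particular
real dataset.

## Numerical choices and degenerate inputs

- Cholesky diagonals are clipped to exp([−20, 15]); σ² is floored at
  1e-30, so noise-free data give exact fits instead of overflow.
- Collinear fixed-effect designs raise an error naming the columns; a
  one-sex cohort makes the sex test raise rather than return a vacuous p.
- The k-median DP breaks median ties toward the lower value; out-of-sample
  times are assigned by the midpoint edges between adjacent clusters.
- Bootstrap replicates are relabelled so a subject drawn twice acts as two
  independent subjects; non-converging replicates are dropped and counted,
  with a warning past 5%.
- PCA keeps constant columns (warning) and clips tiny negative eigenvalues
  to zero.

## Problem sizes used by the test suite

Simulation-based checks run at the design scale where the property demands
it (n = 231 for recovery and LRT calibration; 100 null replicates;
10 seeds for bivariate recovery and null calibration at n = 300 with
2 × 1500 Gibbs iterations; B = 200 bootstrap for the separated-regions
mass) and at reduced scale for properties that do not depend on n
(coverage spot-checks, oracle equivalences on ≤ 5 subjects, planted-outlier
QC at n = 50).  These sizes are stated here so results are reproducible as
given.

## Known limitations

- The improper covariance prior can be slow-mixing when slope variances
  are tiny relative to the residual; the proper-prior fallback changes the
  estimand slightly and is therefore flagged on the fit object.
- The mean-of-means slope estimator is biased toward zero; no shrinkage
  correction is applied, by design (fidelity to the described procedure
  over optimality).
- Wald CIs for variance-component-adjacent quantities (random slope SD)
  are not provided; the LRT is the supported inference for slope variance.
- The exclusion-rule thresholds are scale-dependent and should be
  re-examined for data not scaled to percent-of-intercept.
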