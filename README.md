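# lgctraj

Latent growth-curve analysis of regional brain-volume trajectories in
aging cohorts: how fast does each structure shrink, how much do people
differ in their rate of decline, and do fast decliners in one region
decline fast in others?

The package is aimed at researchers analysing longitudinal volumetric MRI
panels (a few hundred subjects, a handful of waves over a few years) and
at methodologists who want a fully synthetic, self-contained testbed for
this class of models.

## What it computes

For long-format data (one row per subject × occasion: id, years since
baseline, entry age, sex, ICV, one column per regional volume in mm³):

1. **Percent scaling** — each region is divided by its model-implied
   volume at age 65 (×100), so slopes read as % of the age-65 volume per
   year across regions of very different size.
2. **Univariate random-slope models** — per region,
   `y ~ 1 + age_c + age_c² + icv_c + t + t:age_c + t:icv_c` with random
   intercept and slope per subject, ML-fit by a profiled log-Cholesky
   optimizer.  Entry age (`age_c`, centered at 65) carries between-person
   differences; time-in-study `t` carries within-person change.  Includes
   the boundary-corrected LRT for the random-slope variance (50:50
   χ²₁:χ²₂ mixture) and a 2-df sex-difference LRT.
3. **Influence QC** — per-subject Cook's distance (case-deletion refits)
   and log-likelihood contribution; exclusion when D > 0.5 and ℓ < −7.5,
   or D > 1 and ℓ < −4.
4. **20-year extrapolation** — loss₂₀ = 20·βₛ + 160·βₛₐ (five 4-year
   segments, slope refreshed at 65/69/73/77/81), with a subject-resampling
   bootstrap for CIs and a pairwise "which region declines faster" mass
   matrix.
5. **Bivariate Bayesian growth models** — per region pair, a Gibbs sampler
   for the joint covariance of the two random intercepts and slopes
   (flat/improper Inverse-Wishart priors with a guarded proper fallback),
   yielding the posterior of the slope–slope correlation ρ_ss, starred by
   the posterior mass beyond zero (\* < 0.05, \*\* < 0.005, \*\*\* < 0.0005),
   plus plausible values of each subject's latent slope.
6. **Plausible-value PCA** — a subjects × regions slope matrix (mean of
   means over the bivariate fits), residualized on ICV, sex and entry
   age, eigendecomposed on its covariance.
7. **Synthetic cohorts** — a generator that emulates the study design
   (n = 231, entry age 64–87, waves 0/1/2/4 yr with jitter, MAR dropout
   to 72% retention, cross-region random-slope correlations), so the full
   pipeline runs and is tested without any data download.

A packaged reference table (`lgctraj.load_reference_slopes()`) holds the
published per-region slope estimates from a 231-subject healthy-aging
panel; it feeds the extrapolation identity and provides realistic
generator presets.

## Worked example

```python
from lgctraj import (CohortDesign, RegionTruth, GrowthModelSpec,
                     generate_cohort, scale_to_percent, fit_univariate,
                     lrt_random_slope, loss20, slope_at_age)

design = CohortDesign(n_subjects=231, seed=42)
truth = RegionTruth.from_reference(["hippocampus", "caudate", "thalamus"],
                                   slope_corr=0.5)
cohort = scale_to_percent(generate_cohort(design, truth))

fit = fit_univariate(cohort, GrowthModelSpec(region="hippocampus"))
red = fit_univariate(cohort, GrowthModelSpec(region="hippocampus",
                                             random_slope=False))
stat, p = lrt_random_slope(fit, red)
print(f"slope at 65      : {fit.slope:+.3f} %/yr")
print(f"slope x entry-age: {fit.slope_x_entry_age:+.4f} %/yr per year")
print(f"random slope SD  : {fit.random_slope_sd:.3f} %/yr   (LRT p = {p:.2e})")
print(f"loss 20 years    : {loss20(fit.slope, fit.slope_x_entry_age):+.2f} %")
print(f"slope at age 70  : {slope_at_age(fit, 70):+.3f} %/yr")
```

prints

```
slope at 65      : -0.780 %/yr
slope x entry-age: -0.0412 %/yr per year
random slope SD  : 0.473 %/yr   (LRT p = 7.46e-20)
loss 20 years    : -22.20 %
slope at age 70  : -0.986 %/yr
```

The cohort was generated with hippocampus-like truth (slope −0.784 %/yr,
interaction −0.040, random-slope SD 0.441), and the fit recovers it: the
average hippocampus loses ~0.78% of its age-65 volume per year at 65,
declines faster in later-entering subjects, and individuals genuinely
differ in their rate (random-slope SD ≈ 0.47 %/yr, decisively nonzero by
the boundary LRT).  Compounded with its acceleration, the expected loss
from 65 to 85 is ~22% of the age-65 volume.

The same analyses are available from the shell:

```bash
lgctraj simulate --n 231 --regions hippocampus,caudate --out cohort.csv
lgctraj fit cohort.csv
lgctraj extrapolate cohort.csv -B 200 --seed 1
lgctraj bivar cohort.csv --pair hippocampus caudate
lgctraj run --out results/  # full pipeline from one config/seed
```

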