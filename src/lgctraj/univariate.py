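"""Univariate linear random-slope growth models.

The standard model for one region regresses its (percent-scaled) volume on
an intercept, entry-age (centered at 65), entry-age squared, grand-mean
centered ICV, time-in-study, time x entry-age and time x ICV, with a
person-specific random intercept and random slope.  The optional sex
extension adds sex main and interaction terms.  Fitting is full-information
maximum likelihood, so subjects contribute all and only their observed
waves (valid under missingness at random).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import Cohort
from .lmm import LMMData, LMMResult, fit_lmm

__all__ = [
    "GrowthModelSpec",
    "GrowthFit",
    "build_lmm_data",
    "fit_univariate",
    "lrt_random_slope",
    "sex_effect_test",
    "slope_at_age",
]


@dataclass
class GrowthModelSpec:
    """Covariate and random-effect structure of the growth model."""

    region: str
    sex_extension: bool = False
    random_slope: bool = True
    age_center: float = 65.0
    #: ICV centering constant; None means grand mean of the cohort
    icv_center: float | None = None
    n_starts: int = 3

    def x_names(self) -> list[str]:
        names = ["intercept", "age_c", "age_c2", "icv_c", "time", "time:age_c", "time:icv_c"]
        if self.sex_extension:
            names += ["sex", "sex:age_c", "sex:age_c2", "sex:time", "sex:time:age_c"]
        return names


def build_lmm_data(cohort: Cohort, spec: GrowthModelSpec) -> tuple[LMMData, float]:
    """Assemble padded per-subject arrays for the spec'd model.

    Returns the data and the ICV centering constant actually used.
    """
    df = cohort.data.dropna(subset=[spec.region])
    icv0 = spec.icv_center
    if icv0 is None:
        icv0 = float(cohort.subjects["icv"].mean())
    ys, Xs, Zs, ids = [], [], [], []
    for sid, g in df.groupby("subject_id", sort=True):
        t = g["time_years"].to_numpy(float)
        age_c = g["entry_age"].to_numpy(float) - spec.age_center
        icv_c = g["icv"].to_numpy(float) - icv0
        cols = [np.ones_like(t), age_c, age_c**2, icv_c, t, t * age_c, t * icv_c]
        if spec.sex_extension:
            male = (g["sex"].to_numpy() == "M").astype(float)
            cols += [male, male * age_c, male * age_c**2, male * t, male * t * age_c]
        X = np.column_stack(cols)
        Z = np.column_stack([np.ones_like(t), t]) if spec.random_slope else np.ones((len(t), 1))
        ys.append(g[spec.region].to_numpy(float))
        Xs.append(X)
        Zs.append(Z)
        ids.append(sid)
    return LMMData.from_blocks(ys, Xs, Zs, ids, spec.x_names()), icv0


@dataclass
class GrowthFit:
    """Univariate fit: fixed effects, variance components, per-subject posteriors."""

    spec: GrowthModelSpec
    result: LMMResult
    icv_center: float

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.result.beta, index=self.result.x_names)

    @property
    def se(self) -> pd.Series:
        return pd.Series(self.result.se_beta(), index=self.result.x_names)

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        lo = self.beta - z * self.se
        hi = self.beta + z * self.se
        return pd.DataFrame({"lo": lo, "hi": hi})

    @property
    def slope(self) -> float:
        """Annual change at entry age 65 (and mean ICV), %/yr."""
        return float(self.beta["time"])

    @property
    def slope_x_entry_age(self) -> float:
        return float(self.beta["time:age_c"])

    @property
    def intercept(self) -> float:
        """Fitted population level at entry age 65, mean ICV, baseline."""
        return float(self.beta["intercept"])

    @property
    def G(self) -> np.ndarray:
        return self.result.G

    @property
    def random_slope_sd(self) -> float:
        if not self.spec.random_slope:
            return 0.0
        return float(np.sqrt(max(self.result.G[1, 1], 0.0)))

    @property
    def sigma2(self) -> float:
        return self.result.sigma2

    @property
    def loglik(self) -> float:
        return self.result.loglik

    @property
    def loglik_i(self) -> pd.Series:
        return pd.Series(self.result.loglik_i, index=self.result.subject_ids)

    @property
    def ranef(self) -> pd.DataFrame:
        cols = ["u_intercept", "u_slope"] if self.spec.random_slope else ["u_intercept"]
        return pd.DataFrame(self.result.ranef_mean, index=self.result.subject_ids, columns=cols)

    @property
    def converged(self) -> bool:
        return self.result.converged


def fit_univariate(cohort: Cohort, spec: GrowthModelSpec, theta0=None) -> GrowthFit:
    """ML fit of the random-slope growth model for one region."""
    if spec.region not in cohort.regions:
        raise KeyError(f"region {spec.region!r} not in cohort")
    data, icv0 = build_lmm_data(cohort, spec)
    res = fit_lmm(data, random_slope=spec.random_slope, n_starts=spec.n_starts, theta0=theta0)
    return GrowthFit(spec=spec, result=res, icv_center=icv0)


def lrt_random_slope(fit_full: GrowthFit, fit_reduced: GrowthFit) -> tuple[float, float]:
    """Boundary-corrected LRT for the random-slope variance.

    Removing the slope variance together with the intercept-slope
    covariance puts one parameter on the boundary, so the statistic is
    referred to a 50:50 mixture of chi2(1) and chi2(2).
    """
    if fit_full.spec.region != fit_reduced.spec.region:
        raise ValueError("fits are for different regions")
    if not fit_full.spec.random_slope or fit_reduced.spec.random_slope:
        raise ValueError("expected (full with random slope, reduced without)")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < -1e-4:
        raise RuntimeError(
            f"full-model log-likelihood below reduced ({stat/2:.4g}); optimizer failure"
        )
    stat = max(stat, 0.0)
    p = 0.5 * chi2.sf(stat, 1) + 0.5 * chi2.sf(stat, 2)
    if stat == 0.0:
        p = 1.0
    return float(stat), float(p)


def sex_effect_test(cohort: Cohort, spec: GrowthModelSpec) -> tuple[float, float]:
    """LRT for sex differences in decline: sex x time and sex x time x age.

    Both models carry the sex level terms; the test removes only the two
    slope-related sex interactions (2 df chi-square).
    """
    sexes = set(cohort.subjects["sex"])
    if len(sexes) < 2:
        raise ValueError(f"no sex contrast: cohort contains only {sorted(sexes)}")
    full_spec = GrowthModelSpec(
        region=spec.region, sex_extension=True, random_slope=spec.random_slope,
        age_center=spec.age_center, icv_center=spec.icv_center, n_starts=spec.n_starts,
    )
    data_full, icv0 = build_lmm_data(cohort, full_spec)
    res_full = fit_lmm(data_full, random_slope=full_spec.random_slope, n_starts=spec.n_starts)
    # reduced: drop sex:time and sex:time:age_c columns
    keep = [i for i, nm in enumerate(full_spec.x_names()) if nm not in ("sex:time", "sex:time:age_c")]
    data_red = LMMData(
        y=data_full.y, X=data_full.X[:, :, keep], Z=data_full.Z, mask=data_full.mask,
        subject_ids=data_full.subject_ids,
        x_names=[full_spec.x_names()[i] for i in keep],
    )
    res_red = fit_lmm(data_red, random_slope=full_spec.random_slope, n_starts=spec.n_starts)
    stat = 2.0 * (res_full.loglik - res_red.loglik)
    if stat < -1e-4:
        raise RuntimeError("nested log-likelihood ordering violated; optimizer failure")
    stat = max(stat, 0.0)
    return float(stat), float(chi2.sf(stat, 2))


def slope_at_age(fit: GrowthFit, age: float) -> float:
    """Expected annual change (%/yr) at a given entry age.

    Ages outside the sampled 64-87 range extrapolate linearly (a warning
    is emitted).
    """
    if not 64.0 <= age <= 87.0:
        import warnings

        warnings.warn(f"age {age} outside the sampled range 64-87; extrapolating")
    return float(fit.slope + fit.slope_x_entry_age * (age - fit.spec.age_center))
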