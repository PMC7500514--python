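"""Univariate growth model: oracle equivalences and contract behaviour."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lgctraj import (
    CohortDesign,
    GrowthModelSpec,
    RegionTruth,
    fit_univariate,
    generate_cohort,
    lrt_random_slope,
    sex_effect_test,
    slope_at_age,
)
from lgctraj.lmm import LMMData, _gamma_from_theta, fit_lmm, loglik_by_subject, profiled_deviance
from lgctraj.univariate import build_lmm_data

from conftest import make_cohort


def test_zero_noise_fit_recovers_generating_parameters():
    design = CohortDesign(
        n_subjects=8, seed=0, time_jitter_sd=0.0, retention_final=1.0,
        extra_wave_fraction=0.0,
    )
    truth = RegionTruth.create(
        ["a"], slope=-0.5, slope_x_entry_age=-0.02,
        random_slope_sd=0.0, random_intercept_sd=0.0, residual_sd=0.0,
    )
    cohort = generate_cohort(design, truth)
    cohort.scale = "percent_of_intercept65"
    cohort.data["a"] = cohort.data["a"] / truth.intercept_65[0] * 100
    fit = fit_univariate(cohort, GrowthModelSpec(region="a"))
    assert fit.slope == pytest.approx(-0.5, abs=1e-6)
    assert fit.slope_x_entry_age == pytest.approx(-0.02, abs=1e-6)
    assert fit.beta["age_c"] == pytest.approx(-0.3, abs=1e-6)
    assert np.all(np.abs(fit.G) < 1e-8)
    assert fit.sigma2 < 1e-12


def test_marginal_likelihood_matches_direct_mvn_density(small_cohort):
    """Per-subject contributions equal a naive multivariate-normal oracle."""
    spec = GrowthModelSpec(region="a")
    data, _ = build_lmm_data(small_cohort, spec)
    idx = np.arange(5)
    tiny = data.subset(idx)
    fit = fit_lmm(tiny, random_slope=True, n_starts=1)
    Gamma = _gamma_from_theta(fit.theta, 2)
    for i in range(5):
        k = int(tiny.mask[i].sum())
        y, X, Z = tiny.y[i, :k], tiny.X[i, :k], tiny.Z[i, :k]
        Sigma = fit.sigma2 * (Z @ Gamma @ Z.T + np.eye(k))
        oracle = multivariate_normal.logpdf(y, mean=X @ fit.beta, cov=Sigma)
        assert fit.loglik_i[i] == pytest.approx(oracle, abs=1e-8)
    assert fit.loglik == pytest.approx(fit.loglik_i.sum(), abs=1e-8)


def test_profiled_beta_with_vanishing_G_matches_ols(small_cohort):
    """As the relative random-effect covariance goes to zero, the profiled
    fixed effects equal pooled ordinary least squares."""
    from lgctraj.lmm import _profile

    data, _ = build_lmm_data(small_cohort, GrowthModelSpec(region="a"))
    _, beta, _, _ = _profile(np.array([-18.0, 0.0, -18.0]), data)
    mask = data.mask.reshape(-1)
    Xp = data.X.reshape(-1, data.X.shape[2])[mask]
    yp = data.y.reshape(-1)[mask]
    beta_ols = np.linalg.lstsq(Xp, yp, rcond=None)[0]
    np.testing.assert_allclose(beta, beta_ols, atol=1e-6)


def test_cross_check_against_statsmodels_mixedlm(small_cohort):
    """Independent route: statsmodels MixedLM (ML) on the same design."""
    import statsmodels.formula.api as smf

    spec = GrowthModelSpec(region="a")
    fit = fit_univariate(small_cohort, spec)
    df = small_cohort.data.copy()
    df["age_c"] = df["entry_age"] - 65.0
    df["age_c2"] = df["age_c"] ** 2
    df["icv_c"] = df["icv"] - fit.icv_center
    md = smf.mixedlm(
        "a ~ age_c + age_c2 + icv_c + time_years + time_years:age_c + time_years:icv_c",
        df, groups=df["subject_id"], re_formula="~time_years",
    )
    sm_fit = md.fit(reml=False, method="powell", maxiter=2000)
    assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-3)
    assert fit.slope == pytest.approx(sm_fit.params["time_years"], abs=1e-4)
    assert fit.slope_x_entry_age == pytest.approx(
        sm_fit.params["time_years:age_c"], abs=1e-4
    )


def test_conditional_slope_shrinkage(small_fit):
    """Variance of the conditional slope means never exceeds the estimated
    random-slope variance."""
    u = small_fit.ranef["u_slope"]
    assert u.var(ddof=0) <= small_fit.G[1, 1] + 1e-10


def test_parameter_recovery_small_bias():
    """Across replicates at reduced scale, the slope estimator is unbiased
    to within 0.05 %/yr."""
    est = []
    for rep in range(8):
        cohort = make_cohort(n=150, seed=200 + rep, slope=-0.784, random_slope_sd=0.441)
        est.append(fit_univariate(cohort, GrowthModelSpec(region="a")).slope)
    assert abs(np.mean(est) - (-0.784)) < 0.05


def test_lrt_zero_statistic_gives_p_one(small_fit):
    stat, p = lrt_random_slope(small_fit, small_fit.__class__(
        spec=GrowthModelSpec(region="a", random_slope=False),
        result=small_fit.result, icv_center=small_fit.icv_center,
    ))
    assert stat == 0.0
    assert p == 1.0


def test_lrt_power_with_substantial_slope_variance():
    """Hippocampus-like random-slope variance is detected essentially always."""
    rejections = 0
    for rep in range(5):
        cohort = make_cohort(n=231, seed=300 + rep, slope=-0.784, random_slope_sd=0.44)
        full = fit_univariate(cohort, GrowthModelSpec(region="a"))
        red = fit_univariate(cohort, GrowthModelSpec(region="a", random_slope=False))
        _, p = lrt_random_slope(full, red)
        rejections += p < 0.05
    assert rejections >= 5 * 0.9


def test_sex_test_null_is_roughly_uniform():
    """With identical male/female slopes the sex LRT p-values should be
    consistent with Uniform(0,1)."""
    ps = []
    for rep in range(20):
        cohort = make_cohort(n=150, seed=400 + rep)
        _, p = sex_effect_test(cohort, GrowthModelSpec(region="a"))
        ps.append(p)
    ps = np.asarray(ps)
    assert (ps < 0.05).mean() <= 0.2
    assert 0.25 < ps.mean() < 0.75


def test_sex_test_detects_planted_slope_difference():
    """A 0.3 %/yr sex difference in slope at n=231 is detectable."""
    ps = []
    for rep in range(5):
        design = CohortDesign(n_subjects=231, seed=500 + rep)
        truth = RegionTruth.create(["a"], slope=-0.6, random_slope_sd=0.3)
        cohort = generate_cohort(design, truth)
        male = cohort.data["sex"] == "M"
        cohort.data.loc[male, "a"] *= (
            1 - 0.003 * cohort.data.loc[male, "time_years"]
        )
        from lgctraj import scale_to_percent

        cohort = scale_to_percent(cohort)
        _, p = sex_effect_test(cohort, GrowthModelSpec(region="a"))
        ps.append(p)
    assert np.median(ps) < 0.05


def test_sex_test_requires_both_sexes(small_cohort):
    cohort = small_cohort.copy()
    cohort.data = cohort.data[cohort.data["sex"] == "M"].reset_index(drop=True)
    with pytest.raises(ValueError, match="contrast"):
        sex_effect_test(cohort, GrowthModelSpec(region="a"))


def test_slope_at_age_linear_combination(small_fit):
    assert slope_at_age(small_fit, 65.0) == pytest.approx(small_fit.slope)
    expected = small_fit.slope + 20 * small_fit.slope_x_entry_age
    assert slope_at_age(small_fit, 85.0) == pytest.approx(expected)


def test_slope_at_age_tabulated_example():
    """beta_s=-0.556, beta_sa=-0.010 at age 85 gives -0.756."""
    from types import SimpleNamespace

    fit = SimpleNamespace(
        slope=-0.556, slope_x_entry_age=-0.010, spec=SimpleNamespace(age_center=65.0)
    )
    assert slope_at_age(fit, 85.0) == pytest.approx(-0.756)


def test_collinear_design_raises_naming_columns(small_cohort):
    data, _ = build_lmm_data(small_cohort, GrowthModelSpec(region="a"))
    X = np.concatenate([data.X, data.X[:, :, [1]]], axis=2)  # duplicate age_c
    dup = LMMData(
        y=data.y, X=X, Z=data.Z, mask=data.mask,
        subject_ids=data.subject_ids, x_names=data.x_names + ["age_c_dup"],
    )
    with pytest.raises(ValueError, match="collinear"):
        fit_lmm(dup)
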