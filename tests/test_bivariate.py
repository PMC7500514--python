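"""Bivariate growth model: conjugacy oracle, symmetry, plausible values."""

import numpy as np
import pytest

from lgctraj import (
    BivariateSpec,
    CohortDesign,
    RegionTruth,
    classify_reliability,
    fit_bivariate,
    generate_cohort,
    plausible_slopes,
)
from lgctraj.bivariate import _prepare_arrays, _run_chain

from conftest import make_cohort


@pytest.fixture(scope="module")
def pair_fit(pair_cohort):
    spec = BivariateSpec("a", "b", n_chains=2, n_iter=1200, seed=3)
    return fit_bivariate(pair_cohort, spec)


@pytest.mark.parametrize(
    "m,stars",
    [(0.03, "*"), (0.0004, "***"), (0.5, "none"), (0.004, "**"), (0.05, "none"),
     (0.0005, "**"), (0.005, "*")],
)
def test_reliability_star_thresholds(m, stars):
    assert classify_reliability(m) == stars


def test_reliability_rejects_invalid_mass():
    with pytest.raises(ValueError):
        classify_reliability(0.7)
    with pytest.raises(ValueError):
        classify_reliability(-0.1)


def test_posterior_beta_matches_gls_oracle_with_fixed_variances():
    """With Psi and Sigma_e frozen, the Gibbs posterior mean of the fixed
    effects must match the closed-form GLS posterior on a tiny cohort."""
    cohort = make_cohort(n=4, seed=10, regions=("a", "b"), random_slope_sd=0.2)
    spec = BivariateSpec("a", "b", seed=0)
    Y, T, mask, cov, ids = _prepare_arrays(cohort, spec)
    psi = np.diag([4.0, 0.09, 4.0, 0.09])
    sigma_e = np.array([[1.0, 0.3], [0.3, 1.0]])
    rng = np.random.default_rng(0)
    _, _, beta_d, *_ = _run_chain(
        Y, T, mask, cov, n_iter=6000, burn=1000, rng=rng,
        fixed_psi=psi, fixed_sigma_e=sigma_e,
    )
    gibbs_mean = beta_d.mean(axis=0)

    # naive oracle: stack each subject's 2m-vector, V_i = Z Psi Z' + I_m (x) Sigma_e
    from lgctraj.bivariate import _design_row

    U = _design_row(cov, T, mask)
    nP = U.shape[2]
    A = np.eye(2 * nP) / 1e10
    c = np.zeros(2 * nP)
    for i in range(Y.shape[0]):
        k = int(mask[i].sum())
        t = T[i, :k]
        Zi = np.zeros((2 * k, 4))
        Xi = np.zeros((2 * k, 2 * nP))
        yi = np.zeros(2 * k)
        for j in range(k):
            Zi[2 * j, :2] = [1.0, t[j]]
            Zi[2 * j + 1, 2:] = [1.0, t[j]]
            Xi[2 * j, :nP] = U[i, j]
            Xi[2 * j + 1, nP:] = U[i, j]
            yi[2 * j] = Y[i, j, 0]
            yi[2 * j + 1] = Y[i, j, 1]
        Vi = Zi @ psi @ Zi.T + np.kron(np.eye(k), sigma_e)
        Vinv = np.linalg.inv(Vi)
        A += Xi.T @ Vinv @ Xi
        c += Xi.T @ Vinv @ yi
    oracle = np.linalg.solve(A, c)
    mc_se = beta_d.std(axis=0, ddof=1) / np.sqrt(200)  # conservative ESS
    assert np.all(np.abs(gibbs_mean - oracle) < 6 * mc_se + 1e-3)


def test_shared_latent_process_gives_high_slope_correlation():
    """Region b = region a's latent trajectory plus independent noise."""
    cohort = make_cohort(n=500, seed=20, regions=("a", "b"), slope_corr=1.0,
                         random_slope_sd=0.4)
    spec = BivariateSpec("a", "b", n_chains=2, n_iter=1200, seed=1)
    fit = fit_bivariate(cohort, spec)
    assert fit.rho_ss_median > 0.9


def test_slope_correlation_recovery(pair_fit):
    assert 0.55 <= pair_fit.rho_ss_median <= 0.85
    assert all(np.isfinite(v) for v in pair_fit.rhat.values())


def test_rho_invariant_to_region_swap(pair_cohort):
    fit_ab = fit_bivariate(pair_cohort, BivariateSpec("a", "b", n_chains=2, n_iter=1200, seed=5))
    fit_ba = fit_bivariate(pair_cohort, BivariateSpec("b", "a", n_chains=2, n_iter=1200, seed=6))
    assert fit_ab.rho_ss_median == pytest.approx(fit_ba.rho_ss_median, abs=0.1)


def test_psi_draws_positive_definite(pair_fit):
    draws = pair_fit.psi_draws.reshape(-1, 4, 4)[::50]
    for P in draws:
        assert np.min(np.linalg.eigvalsh(P)) > 0
    assert np.all(np.abs(pair_fit.rho_ss_draws) <= 1.0)


def test_plausible_values_collapse_without_residual_noise():
    """With (almost) no within-subject error the plausible values pin down
    each subject's realized slope."""
    cohort = make_cohort(
        n=100, seed=30, regions=("a", "b"), slope_corr=0.5,
        random_slope_sd=0.4, residual_sd=0.01,
    )
    fit = fit_bivariate(cohort, BivariateSpec("a", "b", n_chains=2, n_iter=1000, seed=2))
    ps = plausible_slopes(fit, "a")
    # subjects seen once carry no slope information; the limit concerns the rest
    counts = cohort.data.groupby("subject_id").size()
    ids = counts[counts >= 2].index.intersection(ps.index)
    true = cohort.meta["true_slopes"]["a"].loc[ids]
    assert np.corrcoef(ps.loc[ids, "mean"], true)[0, 1] > 0.99
    assert ps.loc[ids, "sd"].median() < 0.05


def test_plausible_mean_tracks_true_slopes(pair_fit, pair_cohort):
    ps = plausible_slopes(pair_fit, "a")
    true = pair_cohort.meta["true_slopes"]["a"].loc[ps.index]
    assert np.corrcoef(ps["mean"], true)[0, 1] > 0.6


def test_baseline_only_subject_keeps_prior_slope_uncertainty():
    """A subject observed once carries (nearly) the marginal slope SD."""
    cohort = make_cohort(n=120, seed=40, regions=("a", "b"), slope_corr=0.5,
                         random_slope_sd=0.4)
    sid = cohort.data["subject_id"].iloc[0]
    cohort.data = cohort.data[
        (cohort.data["subject_id"] != sid) | (cohort.data["time_years"] == 0.0)
    ].reset_index(drop=True)
    fit = fit_bivariate(cohort, BivariateSpec("a", "b", n_chains=2, n_iter=1200, seed=4))
    ps = plausible_slopes(fit, "a")
    marginal_sd = float(np.mean(np.sqrt(fit.psi_draws[:, :, 1, 1])))
    lone = ps.loc[sid, "sd"]
    assert lone > 0.6 * marginal_sd
    assert lone > 1.5 * ps.drop(sid)["sd"].median()


def test_identical_regions_rejected():
    with pytest.raises(ValueError):
        BivariateSpec("a", "a")


def test_unknown_region_in_plausible_slopes(pair_fit):
    with pytest.raises(KeyError):
        plausible_slopes(pair_fit, "nonexistent")
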