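"""Bayesian bivariate latent growth models via Gibbs sampling.

For a pair of regions (A, B), both on the percent scale, the model couples
two linear growth processes through a joint normal distribution of the
4-vector (i_A, s_A, i_B, s_B) of random intercepts and slopes with
covariance Psi, and through a shared 2x2 within-occasion residual
covariance.  Covariates (entry age, entry age squared, ICV, sex) act on
both intercepts and slopes.  Priors follow the flat defaults of common
structural-equation software: Normal(0, 1e10) on regression coefficients
and the improper Inverse-Wishart(0, -p-1) on covariance matrices, which is
uniform over covariance elements; a documented proper-prior fallback
(IW(eps*I, p+1)) guards against the degeneracies that the improper prior
can produce when slope variances are tiny.

All full conditionals are conjugate, so the sampler is a plain Gibbs
scheme, batched with numpy across subjects.  Latent-growth loadings use
binned times (the time-window approach) when a binning is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .binning import TimeBinning
from .cohort import Cohort

__all__ = [
    "BivariateSpec",
    "BivariateFit",
    "fit_bivariate",
    "classify_reliability",
    "plausible_slopes",
    "split_rhat",
]

_PRIOR_BETA_VAR = 1e10


@dataclass
class BivariateSpec:
    """Regions, time handling, and sampler settings for one bivariate fit."""

    region_a: str
    region_b: str
    binning: TimeBinning | None = None  # None: use exact times as loadings
    n_chains: int = 2
    n_iter: int = 20000
    burn_in: int | None = None  # default: half of n_iter
    thin_plausible: int | None = None  # keep <= ~1000 draws per subject
    seed: int = 0
    rhat_threshold: float = 1.05
    #: fallback proper prior IW(eps*I, p+1) if the improper prior degenerates
    fallback_eps: float = 1e-4

    def __post_init__(self):
        if self.region_a == self.region_b:
            raise ValueError("the two regions must differ")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")

    @property
    def burn(self) -> int:
        return self.n_iter // 2 if self.burn_in is None else self.burn_in


def classify_reliability(m: float) -> str:
    """Star rating from the posterior mass on the minority side of zero."""
    if not 0.0 <= m <= 0.5:
        raise ValueError(f"posterior mass beyond zero must lie in [0, 0.5], got {m}")
    if m < 0.0005:
        return "***"
    if m < 0.005:
        return "**"
    if m < 0.05:
        return "*"
    return "none"


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction (split R-hat) for draws shaped (chains, n)."""
    import arviz as az

    r = az.rhat(np.asarray(draws))
    if hasattr(r, "to_array"):  # xarray Dataset in some arviz versions
        r = r.to_array().values.ravel()[0]
    return float(r)


def _prepare_arrays(cohort: Cohort, spec: BivariateSpec):
    """Padded per-subject arrays; occasions missing either region are omitted."""
    df = cohort.data.dropna(subset=[spec.region_a, spec.region_b])
    icv0 = float(cohort.subjects["icv"].mean())
    groups = list(df.groupby("subject_id", sort=True))
    n = len(groups)
    m = max(len(g) for _, g in groups)
    Y = np.zeros((n, m, 2))
    T = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    cov = np.zeros((n, 4))  # age_c, age_c^2, icv_c, sex(male)
    ids = []
    for i, (sid, g) in enumerate(groups):
        k = len(g)
        texact = g["time_years"].to_numpy(float)
        if spec.binning is not None:
            t = spec.binning.binned(texact)
        elif "time_bin" in g.columns:
            t = g["time_bin"].to_numpy(float)
        else:
            t = texact
        Y[i, :k, 0] = g[spec.region_a].to_numpy(float)
        Y[i, :k, 1] = g[spec.region_b].to_numpy(float)
        T[i, :k] = t
        mask[i, :k] = True
        age_c = float(g["entry_age"].iloc[0]) - 65.0
        cov[i] = [age_c, age_c**2, float(g["icv"].iloc[0]) - icv0, float(g["sex"].iloc[0] == "M")]
        ids.append(sid)
    return Y, T, mask, cov, ids


def _design_row(cov: np.ndarray, T: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(n, m, 9) design for one region: intercept part then slope part."""
    n, m = T.shape
    U = np.zeros((n, m, 9))
    ones = mask.astype(float)
    U[:, :, 0] = ones
    for j in range(4):
        U[:, :, 1 + j] = ones * cov[:, j][:, None]
    U[:, :, 5] = T * ones
    for j in range(3):
        # slope covariates: entry age, ICV, sex (no quadratic age on slope)
        c = cov[:, [0, 2, 3][j]]
        U[:, :, 6 + j] = T * ones * c[:, None]
    return U


X_NAMES = [
    "intercept", "age_c", "age_c2", "icv_c", "sex",
    "time", "time:age_c", "time:icv_c", "time:sex",
]


@dataclass
class BivariateFit:
    """Posterior draws and summaries of one bivariate growth model."""

    spec: BivariateSpec
    subject_ids: list
    psi_draws: np.ndarray  # (chains, draws, 4, 4)
    sigma_e_draws: np.ndarray  # (chains, draws, 2, 2)
    beta_draws: np.ndarray  # (chains, draws, 18)
    rho_ss_draws: np.ndarray  # (chains, draws)
    plausible: np.ndarray  # (n_subjects, 4, kept_draws) pooled chains
    plausible_mean: np.ndarray  # (n_subjects, 4) over all post-burn draws
    plausible_sd: np.ndarray
    rhat: dict
    converged: bool
    prior_fallback: bool

    @property
    def rho_ss_median(self) -> float:
        return float(np.median(self.rho_ss_draws))

    def rho_ss_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1 - level) / 2
        lo, hi = np.quantile(self.rho_ss_draws, [a, 1 - a])
        return float(lo), float(hi)

    @property
    def mass_beyond_zero(self) -> float:
        """Posterior mass of rho_ss on the minority side of zero."""
        frac_pos = float(np.mean(self.rho_ss_draws > 0))
        return min(frac_pos, 1.0 - frac_pos)

    @property
    def reliability(self) -> str:
        return classify_reliability(self.mass_beyond_zero)

    def summary(self) -> dict:
        lo, hi = self.rho_ss_interval()
        return {
            "region_a": self.spec.region_a,
            "region_b": self.spec.region_b,
            "rho_ss_median": self.rho_ss_median,
            "rho_ss_lo": lo,
            "rho_ss_hi": hi,
            "mass_beyond_zero": self.mass_beyond_zero,
            "reliability": self.reliability,
            "converged": self.converged,
            "prior_fallback": self.prior_fallback,
        }


def _run_chain(
    Y, T, mask, cov, n_iter, burn, rng, proper_prior_eps=None, keep_every=1,
    fixed_psi=None, fixed_sigma_e=None,
):
    """One Gibbs chain; returns post-burn draws.

    ``fixed_psi``/``fixed_sigma_e`` freeze the variance components (used by
    the conjugacy oracle tests).
    """
    n, m = T.shape
    U = _design_row(cov, T, mask)  # (n, m, 9)
    nP = U.shape[2]
    fmask = mask.astype(float)

    # sufficient statistics that do not change across iterations
    S_uu = np.einsum("nmp,nmq->pq", U, U)

    # initial values: per-region OLS, zero random effects
    beta = np.zeros(2 * nP)
    for r in range(2):
        yr = Y[:, :, r][mask]
        Ur = U[mask.astype(bool)]
        beta[r * nP : (r + 1) * nP] = np.linalg.lstsq(Ur, yr, rcond=None)[0]
    b = np.zeros((n, 4))
    psi = np.diag([25.0, 0.25, 25.0, 0.25]) if fixed_psi is None else fixed_psi.copy()
    sigma_e = np.eye(2) if fixed_sigma_e is None else fixed_sigma_e.copy()

    n_obs_occ = int(mask.sum())
    prior_prec_beta = np.eye(2 * nP) / _PRIOR_BETA_VAR

    kept = n_iter - burn
    psi_d = np.empty((kept, 4, 4))
    se_d = np.empty((kept, 2, 2))
    beta_d = np.empty((kept, 2 * nP))
    # running moments of b + thinned retention
    b_sum = np.zeros((n, 4))
    b_sumsq = np.zeros((n, 4))
    keep_idx = np.arange(0, kept, keep_every)
    b_kept = np.empty((n, 4, len(keep_idx)))
    kk = 0

    for it in range(n_iter):
        W = np.linalg.inv(sigma_e)
        psi_inv = np.linalg.inv(psi)

        # --- per-subject random effects b_i | rest ---
        mu = np.einsum("nmp,p->nm", U, beta[:nP])[:, :, None]
        mu = np.concatenate([mu, np.einsum("nmp,p->nm", U, beta[nP:])[:, :, None]], axis=2)
        R = (Y - mu) * fmask[:, :, None]  # (n, m, 2)
        # Z_j^T W Z_j summed over occasions, built from scalars
        sw_t0 = fmask.sum(axis=1)  # sum 1
        sw_t1 = (T * fmask).sum(axis=1)  # sum t
        sw_t2 = (T * T * fmask).sum(axis=1)  # sum t^2
        M = np.zeros((n, 4, 4))
        for (a_, b_), wab in np.ndenumerate(W):
            # block (region a_, region b_) scaled by W[a_, b_]
            M[:, 2 * a_ + 0, 2 * b_ + 0] += wab * sw_t0
            M[:, 2 * a_ + 0, 2 * b_ + 1] += wab * sw_t1
            M[:, 2 * a_ + 1, 2 * b_ + 0] += wab * sw_t1
            M[:, 2 * a_ + 1, 2 * b_ + 1] += wab * sw_t2
        prec = psi_inv[None, :, :] + M
        WR = np.einsum("ab,nmb->nma", W, R)
        rhs = np.stack(
            [
                WR[:, :, 0].sum(axis=1),
                (WR[:, :, 0] * T).sum(axis=1),
                WR[:, :, 1].sum(axis=1),
                (WR[:, :, 1] * T).sum(axis=1),
            ],
            axis=1,
        )
        cov_b = np.linalg.inv(prec)
        mean_b = np.einsum("nij,nj->ni", cov_b, rhs)
        Lb = np.linalg.cholesky(cov_b)
        b = mean_b + np.einsum("nij,nj->ni", Lb, rng.standard_normal((n, 4)))

        # --- fixed effects beta | rest ---
        fitted_b = np.stack(
            [b[:, 0][:, None] + b[:, 1][:, None] * T, b[:, 2][:, None] + b[:, 3][:, None] * T],
            axis=2,
        ) * fmask[:, :, None]
        Ystar = (Y - fitted_b) * fmask[:, :, None]
        A = np.kron(W, S_uu) + prior_prec_beta
        WY = np.einsum("ab,nmb->nma", W, Ystar)
        c_vec = np.concatenate(
            [np.einsum("nmp,nm->p", U, WY[:, :, 0]), np.einsum("nmp,nm->p", U, WY[:, :, 1])]
        )
        La = np.linalg.cholesky(A)
        mean_beta = np.linalg.solve(A, c_vec)
        z = rng.standard_normal(2 * nP)
        beta = mean_beta + np.linalg.solve(La.T, z)

        # --- Psi | b ---
        if fixed_psi is None:
            S_b = b.T @ b
            if proper_prior_eps is not None:
                psi = invwishart.rvs(df=n + 5, scale=S_b + proper_prior_eps * np.eye(4), random_state=rng)
            else:
                # improper IW(0, -p-1): posterior IW(S_b, n - p - 1)
                psi = invwishart.rvs(df=n - 5, scale=S_b, random_state=rng)

        # --- Sigma_e | residuals (at the freshly drawn beta) ---
        mu_new = np.stack(
            [np.einsum("nmp,p->nm", U, beta[:nP]), np.einsum("nmp,p->nm", U, beta[nP:])],
            axis=2,
        )
        if fixed_sigma_e is None:
            E = (Y - mu_new - fitted_b) * fmask[:, :, None]
            S_e = np.einsum("nma,nmb->ab", E, E)
            if proper_prior_eps is not None:
                sigma_e = invwishart.rvs(df=n_obs_occ + 3, scale=S_e + proper_prior_eps * np.eye(2), random_state=rng)
            else:
                sigma_e = invwishart.rvs(df=n_obs_occ - 3, scale=S_e, random_state=rng)

        if it >= burn:
            j = it - burn
            psi_d[j] = psi
            se_d[j] = sigma_e
            beta_d[j] = beta
            # plausible values of the latent growth factors: covariate part
            # plus the subject's random effect, per draw
            eta = np.empty((n, 4))
            D5 = np.column_stack([np.ones(n), cov])  # 1, age, age2, icv, sex
            G4 = np.column_stack([np.ones(n), cov[:, [0, 2, 3]]])  # 1, age, icv, sex
            eta[:, 0] = D5 @ beta[0:5] + b[:, 0]
            eta[:, 1] = G4 @ beta[5:9] + b[:, 1]
            eta[:, 2] = D5 @ beta[nP : nP + 5] + b[:, 2]
            eta[:, 3] = G4 @ beta[nP + 5 : nP + 9] + b[:, 3]
            b_sum += eta
            b_sumsq += eta * eta
            if kk < len(keep_idx) and j == keep_idx[kk]:
                b_kept[:, :, kk] = eta
                kk += 1

    b_mean = b_sum / kept
    b_sd = np.sqrt(np.maximum(b_sumsq / kept - b_mean**2, 0.0))
    return psi_d, se_d, beta_d, b_mean, b_sd, b_kept


def fit_bivariate(cohort: Cohort, spec: BivariateSpec) -> BivariateFit:
    """Gibbs-sample the bivariate growth model for a pair of regions."""
    for r in (spec.region_a, spec.region_b):
        if r not in cohort.regions:
            raise KeyError(f"region {r!r} not in cohort")
    Y, T, mask, cov, ids = _prepare_arrays(cohort, spec)
    n = Y.shape[0]
    if n - 5 < 4:
        raise ValueError("too few subjects for the improper covariance prior")
    kept = spec.n_iter - spec.burn
    keep_every = spec.thin_plausible or max(1, kept // 500)

    def run(eps):
        psi_c, se_c, beta_c, bm_c, bs_c, bk_c = [], [], [], [], [], []
        for c in range(spec.n_chains):
            rng = np.random.default_rng((spec.seed, c))
            out = _run_chain(
                Y, T, mask, cov, spec.n_iter, spec.burn, rng,
                proper_prior_eps=eps, keep_every=keep_every,
            )
            psi_c.append(out[0]); se_c.append(out[1]); beta_c.append(out[2])
            bm_c.append(out[3]); bs_c.append(out[4]); bk_c.append(out[5])
        return (np.stack(psi_c), np.stack(se_c), np.stack(beta_c),
                np.stack(bm_c), np.stack(bs_c), np.concatenate(bk_c, axis=2))

    prior_fallback = False
    try:
        psi_d, se_d, beta_d, b_mean, b_sd, b_kept = run(None)
        svar = psi_d[:, :, [1, 3], [1, 3]]
        if not np.all(np.isfinite(psi_d)) or np.any(svar <= 0):
            raise FloatingPointError("degenerate covariance draws")
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        prior_fallback = True
        psi_d, se_d, beta_d, b_mean, b_sd, b_kept = run(spec.fallback_eps)

    with np.errstate(invalid="ignore"):
        rho = psi_d[:, :, 1, 3] / np.sqrt(psi_d[:, :, 1, 1] * psi_d[:, :, 3, 3])

    rhats = {"rho_ss": split_rhat(rho)}
    for nm, idx in (("var_sA", (1, 1)), ("var_sB", (3, 3)), ("cov_ss", (1, 3))):
        rhats[nm] = split_rhat(psi_d[:, :, idx[0], idx[1]])
    rhats["resid_corr"] = split_rhat(
        se_d[:, :, 0, 1] / np.sqrt(se_d[:, :, 0, 0] * se_d[:, :, 1, 1])
    )
    converged = all(np.isfinite(v) and v < spec.rhat_threshold for v in rhats.values())

    return BivariateFit(
        spec=spec,
        subject_ids=ids,
        psi_draws=psi_d,
        sigma_e_draws=se_d,
        beta_draws=beta_d,
        rho_ss_draws=rho,
        plausible=b_kept,
        plausible_mean=b_mean.mean(axis=0),
        plausible_sd=np.sqrt((b_sd**2 + b_mean**2).mean(axis=0) - b_mean.mean(axis=0) ** 2),
        rhat=rhats,
        converged=converged,
        prior_fallback=prior_fallback,
    )


def plausible_slopes(fit: BivariateFit, region: str) -> pd.DataFrame:
    """Per-subject plausible-value summaries of the random slope of ``region``.

    Returns a frame indexed by subject with the posterior mean and SD of
    the subject's random slope, plus access to the retained draw set via
    the ``draws`` attribute of the frame (a (subjects, draws) array).
    """
    if region == fit.spec.region_a:
        j = 1
    elif region == fit.spec.region_b:
        j = 3
    else:
        raise KeyError(f"region {region!r} not part of this fit")
    df = pd.DataFrame(
        {"mean": fit.plausible_mean[:, j], "sd": fit.plausible_sd[:, j]},
        index=fit.subject_ids,
    )
    df.attrs["draws"] = fit.plausible[:, j, :]
    return df
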