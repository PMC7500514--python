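"""Profiled maximum-likelihood machinery for linear mixed models.

Fits y_i = X_i beta + Z_i u_i + e_i with u_i ~ N(0, G), e_i ~ N(0, s2 I),
by optimizing the profiled deviance over the log-Cholesky factor of the
relative covariance Gamma = G / s2: for given Gamma, beta has a GLS closed
form and s2 a closed form, so only 1 (random intercept) or 3 (random
intercept + slope) parameters are optimized.  All per-subject operations
are batched by padding every subject to the maximum occasion count, which
keeps a full fit in the tens of milliseconds at cohort scale and makes
case-deletion and bootstrap refits affordable.

This module is deliberately self-contained: the pipeline needs per-subject
log-likelihood contributions, conditional random-effect posteriors, and
warm-started refits, which general-purpose mixed-model interfaces do not
expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["LMMData", "LMMResult", "fit_lmm", "profiled_deviance", "loglik_by_subject"]

_SIGMA2_FLOOR = 1e-30


@dataclass
class LMMData:
    """Padded per-subject arrays for a mixed model.

    ``y`` is (n, m), ``X`` (n, m, p), ``Z`` (n, m, q) with padded rows set
    to zero everywhere and masked out via ``mask`` (n, m).
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    mask: np.ndarray
    subject_ids: list
    x_names: list[str]

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @property
    def n_obs_i(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    @classmethod
    def from_blocks(cls, ys, Xs, Zs, subject_ids, x_names) -> "LMMData":
        n = len(ys)
        m = max(len(y) for y in ys)
        p, q = Xs[0].shape[1], Zs[0].shape[1]
        y = np.zeros((n, m))
        X = np.zeros((n, m, p))
        Z = np.zeros((n, m, q))
        mask = np.zeros((n, m), dtype=bool)
        for i, (yi, Xi, Zi) in enumerate(zip(ys, Xs, Zs)):
            k = len(yi)
            y[i, :k] = yi
            X[i, :k] = Xi
            Z[i, :k] = Zi
            mask[i, :k] = True
        return cls(y=y, X=X, Z=Z, mask=mask, subject_ids=list(subject_ids), x_names=list(x_names))

    def drop_subject(self, sid) -> "LMMData":
        keep = np.array([s != sid for s in self.subject_ids])
        return LMMData(
            y=self.y[keep],
            X=self.X[keep],
            Z=self.Z[keep],
            mask=self.mask[keep],
            subject_ids=[s for s in self.subject_ids if s != sid],
            x_names=self.x_names,
        )

    def subset(self, idx: np.ndarray, relabel: bool = False) -> "LMMData":
        ids = [self.subject_ids[i] for i in idx]
        if relabel:
            ids = list(range(len(idx)))
        return LMMData(
            y=self.y[idx], X=self.X[idx], Z=self.Z[idx], mask=self.mask[idx],
            subject_ids=ids, x_names=self.x_names,
        )


def _gamma_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Relative covariance from the unconstrained log-Cholesky vector."""
    L = np.zeros((q, q))
    if q == 1:
        L[0, 0] = np.exp(np.clip(theta[0], -20, 15))
    else:
        L[0, 0] = np.exp(np.clip(theta[0], -20, 15))
        L[1, 0] = np.clip(theta[1], -1e6, 1e6)
        L[1, 1] = np.exp(np.clip(theta[2], -20, 15))
    return L @ L.T


def _profile(theta, data: LMMData):
    """Profiled quantities at a given theta.

    Returns (deviance, beta, sigma2, byproducts) where byproducts carries
    the per-subject pieces needed by the result object.
    """
    q = data.Z.shape[2]
    Gamma = _gamma_from_theta(np.atleast_1d(theta), q)
    n, m, p = data.X.shape
    V = np.einsum("nmq,qr,nkr->nmk", data.Z, Gamma, data.Z)
    V = V + np.eye(m)[None, :, :]
    sign, logdet = np.linalg.slogdet(V)
    Vinv_X = np.linalg.solve(V, data.X)
    Vinv_y = np.linalg.solve(V, data.y[:, :, None])[:, :, 0]
    XtVX = np.einsum("nmp,nmr->pr", data.X, Vinv_X)
    XtVy = np.einsum("nmp,nm->p", Vinv_X, data.y)
    beta = np.linalg.solve(XtVX, XtVy)
    r = data.y - data.X @ beta
    Vinv_r = np.linalg.solve(V, r[:, :, None])[:, :, 0]
    quad_i = np.einsum("nm,nm->n", r, Vinv_r)
    N = data.n_obs
    sigma2 = max(float(quad_i.sum()) / N, _SIGMA2_FLOOR)
    dev = N * np.log(2 * np.pi * sigma2) + float(logdet.sum()) + N
    by = dict(
        Gamma=Gamma, V=V, logdet_i=logdet, quad_i=quad_i, XtVX=XtVX,
        r=r, Vinv_r=Vinv_r,
    )
    return dev, beta, sigma2, by


def profiled_deviance(theta, data: LMMData) -> float:
    return _profile(theta, data)[0]


@dataclass
class LMMResult:
    """Fitted mixed model: estimates plus per-subject posteriors."""

    beta: np.ndarray
    cov_beta: np.ndarray
    G: np.ndarray  # random-effect covariance (q x q)
    sigma2: float
    loglik: float
    loglik_i: np.ndarray  # per-subject contributions, sums to loglik
    ranef_mean: np.ndarray  # (n, q) conditional means
    ranef_cov: np.ndarray  # (n, q, q) conditional covariances
    theta: np.ndarray
    converged: bool
    n_obs: int
    subject_ids: list
    x_names: list[str]
    optim_message: str = ""

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def loglik_by_subject(theta, beta, sigma2, data: LMMData) -> np.ndarray:
    """Per-subject marginal log-likelihood at arbitrary parameter values."""
    q = data.Z.shape[2]
    Gamma = _gamma_from_theta(np.atleast_1d(theta), q)
    m = data.y.shape[1]
    V = np.einsum("nmq,qr,nkr->nmk", data.Z, Gamma, data.Z) + np.eye(m)[None]
    _, logdet = np.linalg.slogdet(V)
    r = data.y - data.X @ beta
    Vinv_r = np.linalg.solve(V, r[:, :, None])[:, :, 0]
    quad = np.einsum("nm,nm->n", r, Vinv_r)
    n_i = data.n_obs_i
    return -0.5 * (n_i * np.log(2 * np.pi * sigma2) + logdet + quad / sigma2)


def fit_lmm(
    data: LMMData,
    random_slope: bool = True,
    n_starts: int = 3,
    theta0: np.ndarray | None = None,
    tol: float = 1e-8,
) -> LMMResult:
    """Maximize the marginal likelihood over (beta, G, sigma2).

    Optimization is quasi-Newton (L-BFGS-B) on the log-Cholesky scale with
    ``n_starts`` starting points (the default start plus random restarts,
    or a warm start via ``theta0``).
    """
    p = data.X.shape[2]
    if np.linalg.matrix_rank(data.X.reshape(-1, p)[data.mask.reshape(-1)]) < p:
        # name the offending columns for the user
        Xflat = data.X.reshape(-1, p)[data.mask.reshape(-1)]
        bad = []
        for j in range(p):
            others = np.delete(Xflat, j, axis=1)
            resid = Xflat[:, j] - others @ np.linalg.lstsq(others, Xflat[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(Xflat[:, j])):
                bad.append(data.x_names[j])
        raise ValueError(f"singular design matrix; collinear columns: {bad or data.x_names}")

    ndim = 3 if random_slope else 1
    starts = []
    if theta0 is not None:
        starts.append(np.asarray(theta0, float))
    starts.append(np.array([-0.5, 0.0, -1.5][:ndim]))
    rng = np.random.default_rng(12345)
    while len(starts) < max(1, n_starts):
        starts.append(rng.normal(0.0, 1.0, size=ndim) + np.array([0.0, 0.0, -1.0][:ndim]))

    best = None
    for s in starts:
        res = minimize(
            profiled_deviance, s, args=(data,), method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta = np.atleast_1d(best.x)
    dev, beta, sigma2, by = _profile(theta, data)
    Gamma = by["Gamma"]
    G = sigma2 * Gamma
    cov_beta = sigma2 * np.linalg.inv(by["XtVX"])
    n_i = data.n_obs_i
    loglik_i = -0.5 * (
        n_i * np.log(2 * np.pi * sigma2) + by["logdet_i"] + by["quad_i"] / sigma2
    )
    # conditional (posterior) random effects: u | y
    ZG = np.einsum("nmq,qr->nmr", data.Z, Gamma)
    Vinv_ZG = np.linalg.solve(by["V"], ZG)
    u_mean = np.einsum("qr,nr->nq", Gamma, np.einsum("nmq,nm->nq", data.Z, by["Vinv_r"]))
    GZt_Vinv_ZG = np.einsum("nmq,nmr->nqr", ZG, Vinv_ZG)
    u_cov = sigma2 * (Gamma[None] - GZt_Vinv_ZG)
    return LMMResult(
        beta=beta,
        cov_beta=cov_beta,
        G=G,
        sigma2=sigma2,
        loglik=-0.5 * dev,
        loglik_i=loglik_i,
        ranef_mean=u_mean,
        ranef_cov=u_cov,
        theta=theta,
        converged=bool(best.success),
        n_obs=data.n_obs,
        subject_ids=data.subject_ids,
        x_names=data.x_names,
        optim_message=str(best.message),
    )
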