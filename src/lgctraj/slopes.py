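"""Person-specific slope matrix and PCA of its covariance.

One slope estimate per subject and region is obtained as the mean, over
every bivariate model containing the region, of that model's posterior
(plausible-value) mean of the subject's latent slope — the "mean of means"
estimator.  This simple estimator is attenuated (shrinkage pulls extreme
subjects toward the mean) but preserves the covariance pattern, which is
all the PCA needs.  Columns are then adjusted for ICV, sex and entry age
by linear regression, and the principal components of the resulting
covariance matrix summarize how decline co-varies across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bivariate import BivariateFit, plausible_slopes
from .cohort import Cohort

__all__ = ["SlopeMatrix", "PcaResult", "build_slope_matrix", "adjust_covariates", "pca_slopes"]


@dataclass
class SlopeMatrix:
    """Subjects x regions matrix of person-specific slope estimates (%/yr)."""

    values: pd.DataFrame
    #: region -> list of (region_a, region_b) pairs that contributed
    provenance: dict
    adjusted: bool = False


@dataclass
class PcaResult:
    """Covariance-matrix PCA of the slope matrix."""

    eigenvalues: np.ndarray
    explained: np.ndarray  # proportion of variance per component
    loadings: pd.DataFrame  # regions x components, orthonormal columns
    scores: pd.DataFrame  # subjects x components
    cumulative: np.ndarray

    def n_components_for(self, target: float = 0.85) -> int:
        """Smallest component count reaching the target cumulative variance."""
        return int(np.searchsorted(self.cumulative, target) + 1)


def build_slope_matrix(fits: list[BivariateFit]) -> SlopeMatrix:
    """Mean-of-means slope estimates from a collection of bivariate fits."""
    if not fits:
        raise ValueError("no bivariate fits supplied")
    per_region: dict[str, list[pd.Series]] = {}
    provenance: dict[str, list[tuple[str, str]]] = {}
    subject_index = None
    for fit in fits:
        ids = list(fit.subject_ids)
        if subject_index is None:
            subject_index = ids
        elif ids != subject_index:
            raise ValueError("bivariate fits cover different subject sets")
        for region in (fit.spec.region_a, fit.spec.region_b):
            s = plausible_slopes(fit, region)["mean"]
            s = pd.Series(s.to_numpy(), index=s.index)  # shed draw attrs
            per_region.setdefault(region, []).append(s)
            provenance.setdefault(region, []).append((fit.spec.region_a, fit.spec.region_b))
    values = pd.DataFrame(
        {r: pd.concat(cols, axis=1).mean(axis=1) for r, cols in per_region.items()}
    )
    return SlopeMatrix(values=values, provenance=provenance, adjusted=False)


def adjust_covariates(matrix: SlopeMatrix, cohort: Cohort) -> SlopeMatrix:
    """Residualize each region column on {1, ICV, sex, entry age}."""
    subj = cohort.subjects.loc[matrix.values.index]
    X = np.column_stack(
        [
            np.ones(len(subj)),
            subj["icv"].to_numpy(float),
            (subj["sex"].to_numpy() == "M").astype(float),
            subj["entry_age"].to_numpy(float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design (ICV, sex, entry age)")
    Y = matrix.values.to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    values = pd.DataFrame(resid, index=matrix.values.index, columns=matrix.values.columns)
    return SlopeMatrix(values=values, provenance=dict(matrix.provenance), adjusted=True)


def pca_slopes(matrix: SlopeMatrix, warn_unadjusted: bool = True) -> PcaResult:
    """Eigendecomposition of the slope matrix's column covariance.

    Components are ordered by decreasing eigenvalue and signed so the
    largest-magnitude loading of each is positive.  Works on the
    covariance (not correlation) matrix: regions are already on a common
    percent-per-year scale, so large-variance regions should dominate.
    """
    import warnings

    if warn_unadjusted and not matrix.adjusted:
        warnings.warn("PCA on an unadjusted slope matrix; covariate effects included")
    Y = matrix.values.to_numpy(float)
    n, r = Y.shape
    if n < r:
        warnings.warn(f"fewer subjects ({n}) than regions ({r}); covariance is singular")
    const = matrix.values.std(ddof=0) < 1e-12
    if const.any():
        warnings.warn(f"constant slope columns retained: {list(const.index[const])}")
    cov = np.cov(Y, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # deterministic sign: largest-|loading| entry positive
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    total = w.sum() if w.sum() > 0 else 1.0
    explained = w / total
    comp_names = [f"PC{j + 1}" for j in range(len(w))]
    loadings = pd.DataFrame(V, index=matrix.values.columns, columns=comp_names)
    centered = Y - Y.mean(axis=0)
    scores = pd.DataFrame(centered @ V, index=matrix.values.index, columns=comp_names)
    return PcaResult(
        eigenvalues=w,
        explained=explained,
        loadings=loadings,
        scores=scores,
        cumulative=np.cumsum(explained),
    )
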