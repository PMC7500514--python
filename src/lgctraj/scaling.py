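"""Rescale regional volumes to percent of the fitted age-65 intercept.

Each region is divided by the population intercept of its own growth model
(evaluated at entry age 65, grand-mean ICV and baseline) and multiplied by
100, so that afterwards the slope parameter reads directly as the annual
percent change of the age-65 volume.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, PERCENT_SCALE
from .univariate import GrowthModelSpec, fit_univariate

__all__ = ["scale_to_percent"]


def scale_to_percent(
    cohort: Cohort, region: str | list[str] | None = None, random_slope: bool = True
) -> Cohort:
    """Return a cohort with the named region(s) on the percent scale.

    ``region=None`` rescales every region column.  The fitted intercepts
    are recorded in ``cohort.meta['fitted_intercepts']``.  Rescaling an
    already-scaled cohort is harmless (the refitted intercept is ~100).
    """
    if region is None:
        regions = cohort.regions
    elif isinstance(region, str):
        regions = [region]
    else:
        regions = list(region)
    out = cohort.copy()
    intercepts = dict(out.meta.get("fitted_intercepts", {}))
    for r in regions:
        if r not in cohort.regions:
            raise KeyError(f"region {r!r} not in cohort")
        fit = fit_univariate(out, GrowthModelSpec(region=r, random_slope=random_slope))
        if not np.isfinite(fit.intercept) or fit.intercept <= 0:
            raise ValueError(
                f"non-positive fitted intercept ({fit.intercept:.4g}) for region {r!r}"
            )
        out.data[r] = out.data[r] / fit.intercept * 100.0
        intercepts[r] = fit.intercept
    out.meta["fitted_intercepts"] = intercepts
    out.scale = PERCENT_SCALE
    return out
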