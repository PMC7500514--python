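import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from lgctraj import (
    CohortDesign,
    GrowthModelSpec,
    RegionTruth,
    fit_univariate,
    generate_cohort,
    scale_to_percent,
)


def make_cohort(
    n=120,
    seed=0,
    regions=("a",),
    scaled=True,
    **truth_kwargs,
):
    """Convenience builder for small synthetic cohorts."""
    defaults = dict(slope=-0.6, random_slope_sd=0.3, residual_sd=1.0)
    defaults.update(truth_kwargs)
    design = CohortDesign(n_subjects=n, seed=seed)
    truth = RegionTruth.create(list(regions), **defaults)
    cohort = generate_cohort(design, truth)
    return scale_to_percent(cohort) if scaled else cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-region percent-scale cohort, n=60."""
    return make_cohort(n=60, seed=5)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    return fit_univariate(small_cohort, GrowthModelSpec(region="a"))


@pytest.fixture(scope="session")
def pair_cohort():
    """Two correlated regions (true slope-slope correlation 0.7), n=300."""
    return make_cohort(
        n=300, seed=2, regions=("a", "b"), slope_corr=0.7, random_slope_sd=0.4
    )
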