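"""Synthetic longitudinal cohorts of regional brain volumes.

Generates long-format cohorts with the structure the downstream analysis
assumes: subjects enter at age 64-87, are measured at planned waves
0/1/2/4 years (with small positive timing jitter and an optional extra
wave near 3 years for a minority), and drop out monotonically under a
missing-at-random hazard, so that roughly 72% remain at the final wave.
Each region's trajectory follows a linear random-intercept/random-slope
model on the percent-of-age-65-volume scale, with covariate effects of
entry age, entry age squared and intracranial volume (ICV) on the level,
entry age and ICV on the slope, and a specified cross-region correlation
matrix for the random slopes.  Volumes are converted back to mm^3 via the
region's age-65 intercept, so the scaling stage downstream has real work
to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .reference import load_reference_slopes

__all__ = [
    "CohortDesign",
    "RegionTruth",
    "Cohort",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
]

#: columns that identify an observation row; everything else is a region volume
ID_COLS = ["subject_id", "time_years", "entry_age", "sex", "icv"]

RAW_SCALE = "raw_mm3"
PERCENT_SCALE = "percent_of_intercept65"

# rough bilateral volumes (mm^3) for regions commonly simulated; anything
# absent falls back to a generic 10 cm^3 structure
_TYPICAL_VOLUMES = {
    "hippocampus": 8500.0,
    "amygdala": 3400.0,
    "thalamus": 15000.0,
    "caudate": 7200.0,
    "putamen": 10200.0,
    "pallidum": 3600.0,
    "accumbens": 1100.0,
    "entorhinal": 3800.0,
    "temporal_pole": 4600.0,
    "para_hippocampal": 4200.0,
    "insula": 13500.0,
    "cerebellum_cortex": 105000.0,
    "brain_stem": 21000.0,
}


@dataclass
class CohortDesign:
    """Study design of a simulated cohort.

    Defaults emulate a healthy-aging panel: 231 subjects aged 64-87 at
    entry (mean 70.8), four planned waves at 0/1/2/4 years with small
    positive timing jitter, a 10% minority with an additional wave near
    3 years, and MAR dropout to 72% retention at the final wave.
    """

    n_subjects: int = 231
    wave_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    time_jitter_sd: float = 0.08
    entry_age_range: tuple[float, float] = (64.0, 87.0)
    entry_age_mean: float = 70.8
    entry_age_sd: float = 5.0
    female_fraction: float = 113 / 231
    icv_mean: float = 1.45e6
    icv_sd: float = 1.3e5
    retention_final: float = 0.72
    #: MAR logit coefficients of the per-wave dropout hazard on the
    #: standardized last-observed mean volume and standardized entry age
    dropout_vol_coef: float = -0.5
    dropout_age_coef: float = 0.5
    extra_wave_time: float = 3.0
    extra_wave_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.wave_times, float)
        if w[0] != 0.0 or np.any(np.diff(w) <= 0):
            raise ValueError("wave_times must be strictly increasing and start at 0")
        if not 0.0 < self.retention_final <= 1.0:
            raise ValueError("retention_final must lie in (0, 1]")
        lo, hi = self.entry_age_range
        if not lo <= self.entry_age_mean <= hi:
            raise ValueError("entry_age_range must contain entry_age_mean")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


@dataclass
class RegionTruth:
    """Generating parameters for one or more regions.

    Fixed effects are expressed on the percent-of-age-65-volume scale:
    ``slope`` is %/yr at entry age 65, ``slope_x_entry_age`` is %/yr per
    year of entry age, ``beta_*`` act on the level.  ``slope_corr`` is the
    cross-region correlation matrix of the random slopes.
    """

    regions: list[str]
    intercept_65: np.ndarray  # mm^3
    slope: np.ndarray  # %/yr at entry age 65
    slope_x_entry_age: np.ndarray  # %/yr per year of entry age
    slope_x_icv: np.ndarray  # %/yr per mm^3 of centered ICV
    beta_entry_age: np.ndarray  # % per year of entry age
    beta_entry_age2: np.ndarray
    beta_icv: np.ndarray  # % per mm^3 of centered ICV
    random_intercept_sd: np.ndarray  # %
    random_slope_sd: np.ndarray  # %/yr
    intercept_slope_corr: np.ndarray
    residual_sd: np.ndarray  # %
    slope_corr: np.ndarray  # regions x regions

    @classmethod
    def create(
        cls,
        regions: list[str],
        *,
        slope_corr: np.ndarray | float = 0.5,
        **params,
    ) -> "RegionTruth":
        """Build a truth object, broadcasting scalars over regions.

        Unspecified parameters take field defaults; ``slope_corr`` given as
        a scalar means an exchangeable correlation at that value.
        """
        r = len(regions)
        defaults = dict(
            intercept_65=np.array(
                [_TYPICAL_VOLUMES.get(name, 10000.0) for name in regions]
            ),
            slope=-0.5,
            slope_x_entry_age=0.0,
            slope_x_icv=0.0,
            beta_entry_age=-0.3,
            beta_entry_age2=-0.01,
            beta_icv=3e-5,
            random_intercept_sd=6.0,
            random_slope_sd=0.3,
            intercept_slope_corr=0.0,
            residual_sd=1.0,
        )
        defaults.update(params)
        arrays = {
            k: np.broadcast_to(np.asarray(v, float), (r,)).copy()
            for k, v in defaults.items()
        }
        if np.isscalar(slope_corr):
            R = np.full((r, r), float(slope_corr))
            np.fill_diagonal(R, 1.0)
        else:
            R = np.asarray(slope_corr, float)
        return cls(regions=list(regions), slope_corr=R, **arrays)

    @classmethod
    def from_reference(
        cls, regions: list[str], *, slope_corr: np.ndarray | float = 0.5, **overrides
    ) -> "RegionTruth":
        """Truth presets taken from the published regional estimates."""
        ref = load_reference_slopes()
        missing = [r for r in regions if r not in ref.index]
        if missing:
            raise KeyError(f"regions not in reference table: {missing}")
        sub = ref.loc[list(regions)]
        params = dict(
            slope=sub["slope"].to_numpy(),
            slope_x_entry_age=sub["slope_x_entry_age"].to_numpy(),
            random_slope_sd=sub["random_slope_sd"].to_numpy(),
        )
        params.update(overrides)
        return cls.create(list(regions), slope_corr=slope_corr, **params)

    def validate(self) -> None:
        R = self.slope_corr
        r = len(self.regions)
        if R.shape != (r, r):
            raise ValueError("slope_corr must be regions x regions")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("slope_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("slope_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-8:
            raise ValueError("slope_corr must be positive semi-definite")
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(np.abs(self.intercept_slope_corr) > 1):
            raise ValueError("intercept_slope_corr must lie in [-1, 1]")
        if np.any(self.intercept_65 <= 0):
            raise ValueError("intercept_65 must be positive")


class Cohort:
    """Long-format longitudinal observations plus subject covariates.

    ``data`` has one row per subject x occasion with columns
    ``subject_id, time_years, entry_age, sex, icv`` followed by one column
    per region; a missing wave is an absent row.  ``scale`` records whether
    volumes are raw mm^3 or percent of the fitted age-65 intercept.
    """

    def __init__(self, data: pd.DataFrame, scale: str = RAW_SCALE, meta: dict | None = None):
        self.data = data.reset_index(drop=True)
        self.scale = scale
        self.meta = dict(meta or {})

    @property
    def regions(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLS and c != "time_bin"]

    @property
    def subjects(self) -> pd.DataFrame:
        base = self.data.sort_values("time_years").groupby("subject_id").first()
        return base[["entry_age", "sex", "icv"]]

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.scale, dict(self.meta))

    def validate(self) -> None:
        df = self.data
        for col in ID_COLS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if not self.regions:
            raise ValueError("cohort has no region columns")
        if df.duplicated(["subject_id", "time_years"]).any():
            raise ValueError("duplicate (subject, time) rows")
        has_baseline = df.groupby("subject_id")["time_years"].min()
        if (has_baseline > 0).any():
            bad = has_baseline[has_baseline > 0].index.tolist()[:5]
            raise ValueError(f"subjects without a baseline (time 0) record: {bad}")
        if (df["entry_age"] < 64 - 1e-9).any():
            raise ValueError("entry_age below 64")
        if (df["time_years"] < 0).any():
            raise ValueError("negative time_years")


def _slope_factor(truth: RegionTruth) -> np.ndarray:
    """Square-root factor of the cross-region random-slope covariance."""
    D = np.diag(truth.random_slope_sd)
    cov = D @ truth.slope_corr @ D
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _calibrate_dropout_intercept(
    design: CohortDesign, z_vol0: np.ndarray, z_age: np.ndarray
) -> float:
    """Find the hazard intercept giving the requested final retention.

    Uses the baseline volume score as a stand-in for the evolving
    last-observed score; the discrepancy is negligible at the default
    coefficient sizes.
    """
    n_steps = len(design.wave_times) - 1
    if n_steps == 0 or design.retention_final >= 1.0:
        return -np.inf
    lin = design.dropout_vol_coef * z_vol0 + design.dropout_age_coef * z_age

    def retention(alpha: float) -> float:
        return float(np.mean((1.0 - expit(alpha + lin)) ** n_steps))

    lo, hi = -30.0, 30.0
    if not retention(lo) >= design.retention_final >= retention(hi):
        raise ValueError(
            "retention_final is infeasible under the dropout model coefficients"
        )
    return brentq(lambda a: retention(a) - design.retention_final, lo, hi, xtol=1e-10)


def generate_cohort(design: CohortDesign, truth: RegionTruth) -> Cohort:
    """Simulate a long-format cohort under the given design and truth.

    Returns a :class:`Cohort` on the raw mm^3 scale.  ``cohort.meta``
    carries the latent simulation state used by self-checks: realized
    per-subject slopes (``true_slopes``), random effects, the complete
    pre-dropout percent-scale table (``complete_percent``) and the applied
    dropout hazard intercept.
    """
    design.validate()
    truth.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects
    regions = truth.regions
    nr = len(regions)

    lo, hi = design.entry_age_range
    a, b = (lo - design.entry_age_mean) / design.entry_age_sd, (
        hi - design.entry_age_mean
    ) / design.entry_age_sd
    entry_age = truncnorm.rvs(
        a, b, loc=design.entry_age_mean, scale=design.entry_age_sd, size=n, random_state=rng
    )
    female = rng.random(n) < design.female_fraction
    sex = np.where(female, "F", "M")
    icv = rng.normal(design.icv_mean, design.icv_sd, size=n)
    icv = np.clip(icv, 0.5 * design.icv_mean, None)
    # women have smaller heads on average; a modest shift keeps ICV the
    # covariate that absorbs sex-related volume differences
    icv -= np.where(female, 0.5, -0.5) * 0.6 * design.icv_sd

    # random effects: slopes jointly across regions, intercepts coupled
    # within region through intercept_slope_corr
    F = _slope_factor(truth)
    u1 = rng.standard_normal((n, nr)) @ F.T
    eps0 = rng.standard_normal((n, nr))
    rho = truth.intercept_slope_corr
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            truth.random_slope_sd > 0,
            truth.random_intercept_sd / np.where(truth.random_slope_sd > 0, truth.random_slope_sd, 1.0),
            0.0,
        )
    u0 = rho * ratio * u1 + np.sqrt(1.0 - rho**2) * truth.random_intercept_sd * eps0

    # observation times
    planned = np.asarray(design.wave_times, float)
    times = []
    has_extra = rng.random(n) < design.extra_wave_fraction
    for i in range(n):
        jit = np.abs(rng.normal(0.0, design.time_jitter_sd, size=len(planned) - 1))
        t = np.concatenate([[0.0], planned[1:] + jit])
        if has_extra[i] and design.extra_wave_time not in planned:
            extra = design.extra_wave_time + abs(rng.normal(0.0, design.time_jitter_sd))
            t = np.sort(np.concatenate([t, [extra]]))
        times.append(t)

    age_c = entry_age - 65.0
    icv_c = icv - design.icv_mean
    person_slope = (
        truth.slope[None, :]
        + truth.slope_x_entry_age[None, :] * age_c[:, None]
        + truth.slope_x_icv[None, :] * icv_c[:, None]
        + u1
    )
    level = (
        100.0
        + truth.beta_entry_age[None, :] * age_c[:, None]
        + truth.beta_entry_age2[None, :] * age_c[:, None] ** 2
        + truth.beta_icv[None, :] * icv_c[:, None]
        + u0
    )

    ids = [f"S{i + 1:04d}" for i in range(n)]
    pct_by_subject = []
    for i in range(n):
        t = times[i]
        e = rng.normal(0.0, truth.residual_sd, size=(len(t), nr))
        pct_by_subject.append(level[i][None, :] + person_slope[i][None, :] * t[:, None] + e)

    # MAR dropout over planned post-baseline waves; hazard depends on the
    # standardized last observed mean percent volume and entry age
    mean_pct = [p.mean(axis=1) for p in pct_by_subject]
    base_mean = np.array([m[0] for m in mean_pct])
    mu0, sd0 = float(base_mean.mean()), float(base_mean.std(ddof=0)) or 1.0
    z_age = (entry_age - entry_age.mean()) / (entry_age.std(ddof=0) or 1.0)
    z_vol0 = (base_mean - mu0) / sd0
    alpha = _calibrate_dropout_intercept(design, z_vol0, z_age)

    observed_until = np.full(n, np.inf)  # planned time of first missed wave
    if np.isfinite(alpha):
        for i in range(n):
            last_z = z_vol0[i]
            for t_plan in planned[1:]:
                h = expit(
                    alpha
                    + design.dropout_vol_coef * last_z
                    + design.dropout_age_coef * z_age[i]
                )
                if rng.random() < h:
                    observed_until[i] = t_plan
                    break
                # update with the value observed at (about) this wave
                j = int(np.argmin(np.abs(times[i] - t_plan)))
                last_z = (mean_pct[i][j] - mu0) / sd0

    # a wave is kept if its planned time precedes the first missed planned
    # wave; jittered times map back to the nearest planned (or extra) wave
    ref_waves = np.sort(np.unique(np.concatenate([planned, [design.extra_wave_time]])))
    complete_rows, observed_rows = [], []
    for i in range(n):
        for j, t in enumerate(times[i]):
            row = (ids[i], float(t), *pct_by_subject[i][j])
            complete_rows.append(row)
            t_plan = ref_waves[np.argmin(np.abs(ref_waves - t))]
            if t_plan < observed_until[i] - 1e-9:
                observed_rows.append(row)
    cols = ["subject_id", "time_years", *regions]
    complete = pd.DataFrame(complete_rows, columns=cols)
    observed = pd.DataFrame(observed_rows, columns=cols)

    # percent -> mm^3
    data = observed.copy()
    subj_cov = pd.DataFrame(
        {"subject_id": ids, "entry_age": entry_age, "sex": sex, "icv": icv}
    )
    data = data.merge(subj_cov, on="subject_id")
    for j, r in enumerate(regions):
        data[r] = data[r] / 100.0 * truth.intercept_65[j]
    data = data[ID_COLS + regions]

    meta = {
        "design": design,
        "truth": truth,
        "true_slopes": pd.DataFrame(person_slope, index=ids, columns=regions),
        "random_slopes": pd.DataFrame(u1, index=ids, columns=regions),
        "random_intercepts": pd.DataFrame(u0, index=ids, columns=regions),
        "complete_percent": complete,
        "dropout_alpha": alpha,
    }
    cohort = Cohort(data, scale=RAW_SCALE, meta=meta)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path, sidecar: bool = True) -> None:
    """Write the long table as CSV, plus a YAML sidecar with design+truth."""
    cohort.data.to_csv(path, index=False)
    if not sidecar:
        return
    info: dict = {"scale": cohort.scale}
    design = cohort.meta.get("design")
    truth = cohort.meta.get("truth")
    if design is not None:
        info["design"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(design).items()
        }
    if truth is not None:
        info["truth"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(truth).items()
        }
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(info, fh, sort_keys=False)


def read_cohort(path, scale: str | None = None) -> Cohort:
    """Read a long-format cohort written by :func:`write_cohort`.

    If ``scale`` is not given, the YAML sidecar (if present) is consulted;
    otherwise raw mm^3 is assumed.
    """
    data = pd.read_csv(path)
    if scale is None:
        scale = RAW_SCALE
        try:
            with open(str(path) + ".yaml") as fh:
                info = yaml.safe_load(fh)
            scale = info.get("scale", RAW_SCALE)
        except FileNotFoundError:
            pass
    cohort = Cohort(data, scale=scale)
    cohort.validate()
    return cohort
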