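"""End-to-end orchestration of the trajectory analysis.

A single config drives: cohort simulation (or ingest), percent scaling,
time binning, influence QC with exclusions, per-region growth fits and
tests, the bootstrap 20-year extrapolation, all-pairs bivariate models,
and the plausible-value PCA.  Every stochastic stage derives its stream
from the single config seed, so a rerun with the same config reproduces
all summary tables bit for bit.  Outputs are delimited text tables plus a
manifest with SHA-256 checksums and the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binning import assign_bins, choose_k, kmedian_bins
from .bivariate import BivariateSpec, fit_bivariate
from .cohort import Cohort, CohortDesign, RegionTruth, generate_cohort, read_cohort, write_cohort
from .extrapolation import bootstrap_loss20, loss20
from .influence import ExclusionRule, apply_exclusion, influence_measures
from .scaling import scale_to_percent
from .slopes import adjust_covariates, build_slope_matrix, pca_slopes
from .univariate import GrowthModelSpec, fit_univariate, lrt_random_slope, sex_effect_test

__all__ = ["RunConfig", "run_pipeline", "fit_region_table", "PipelineError"]

DEFAULT_REGIONS = ["hippocampus", "caudate", "thalamus", "entorhinal", "superior_frontal"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and partial-results manifest."""

    def __init__(self, stage: str, cause: BaseException, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "lgctraj_run"
    input_path: str | None = None  # None: simulate
    regions: list[str] = field(default_factory=lambda: list(DEFAULT_REGIONS))
    n_subjects: int = 231
    seed: int = 0
    slope_corr: float = 0.5
    bins_k: int | None = None  # None: automatic choice
    qc_method: str = "one_step"
    exclusion: ExclusionRule = field(default_factory=ExclusionRule)
    bootstrap_B: int = 200
    run_bivariate: bool = True
    run_pca: bool = True
    mcmc_chains: int = 2
    mcmc_iter: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exclusion" in raw:
            raw["exclusion"] = ExclusionRule(**raw["exclusion"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def fit_region_table(cohort: Cohort, regions: list[str], n_starts: int = 3) -> pd.DataFrame:
    """Per-region summary table: slope, CI, interaction, loss-20, random-slope SD/p, sex p."""
    rows = []
    for r in regions:
        spec = GrowthModelSpec(region=r, n_starts=n_starts)
        fit = fit_univariate(cohort, spec)
        red = fit_univariate(cohort, GrowthModelSpec(region=r, random_slope=False, n_starts=n_starts))
        _, p_rs = lrt_random_slope(fit, red)
        try:
            _, p_sex = sex_effect_test(cohort, spec)
        except ValueError:
            p_sex = np.nan
        ci = fit.ci().loc["time"]
        rows.append(
            {
                "region": r,
                "slope": fit.slope,
                "slope_lo": ci["lo"],
                "slope_hi": ci["hi"],
                "slope_x_entry_age": fit.slope_x_entry_age,
                "loss20": loss20(fit.slope, fit.slope_x_entry_age),
                "random_slope_sd": fit.random_slope_sd,
                "random_slope_p": p_rs,
                "sex_p": p_sex,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": [],
        "files": {},
    }

    def save(df: pd.DataFrame, name: str, index: bool = True):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        manifest["files"][name] = _sha256(path)

    def finish_stage(name: str):
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "ingest"
    try:
        if config.input_path:
            cohort = read_cohort(config.input_path)
        else:
            stage = "simulate"
            design = CohortDesign(n_subjects=config.n_subjects, seed=config.seed)
            truth = RegionTruth.from_reference(config.regions, slope_corr=config.slope_corr)
            cohort = generate_cohort(design, truth)
            write_cohort(cohort, out / "cohort.csv")
            manifest["files"]["cohort.csv"] = _sha256(out / "cohort.csv")
        finish_stage(stage)

        stage = "scale"
        cohort = scale_to_percent(cohort)
        save(
            pd.Series(cohort.meta["fitted_intercepts"], name="intercept_65").to_frame(),
            "fitted_intercepts.tsv",
        )
        finish_stage(stage)

        stage = "bins"
        times = cohort.data["time_years"].to_numpy()
        k = config.bins_k or choose_k(times)
        binning = kmedian_bins(times, k)
        cohort = assign_bins(cohort, binning)
        save(
            pd.DataFrame({"bin_value": binning.bin_values}),
            "time_bins.tsv", index=False,
        )
        finish_stage(stage)

        stage = "qc"
        qc_tables = []
        analysis_cohorts = {}
        for r in config.regions:
            rep = influence_measures(
                cohort, GrowthModelSpec(region=r), method=config.qc_method,
                rule=config.exclusion,
            )
            t = rep.table.copy()
            t.insert(0, "region", r)
            qc_tables.append(t)
            analysis_cohorts[r] = apply_exclusion(rep, cohort)
        save(pd.concat(qc_tables), "influence.tsv")
        finish_stage(stage)

        stage = "fit"
        tables = []
        for r in config.regions:
            tables.append(fit_region_table(analysis_cohorts[r], [r]))
        fit_table = pd.concat(tables)
        save(fit_table, "region_fits.tsv")
        finish_stage(stage)

        stage = "extrapolate"
        extra = bootstrap_loss20(
            cohort, config.regions, B=config.bootstrap_B, seed=config.seed + 1
        )
        save(extra.summary(), "loss20.tsv")
        save(extra.pairwise_mass, "pairwise_mass.tsv")
        finish_stage(stage)

        if config.run_bivariate:
            stage = "bivariate"
            fits = []
            summaries = []
            for i, (ra, rb) in enumerate(itertools.combinations(config.regions, 2)):
                spec = BivariateSpec(
                    region_a=ra, region_b=rb, binning=binning,
                    n_chains=config.mcmc_chains, n_iter=config.mcmc_iter,
                    seed=config.seed + 100 + i,
                )
                fit = fit_bivariate(cohort, spec)
                fits.append(fit)
                summaries.append(fit.summary())
            save(pd.DataFrame(summaries), "bivariate_summary.tsv", index=False)
            corr = pd.DataFrame(
                np.eye(len(config.regions)), index=config.regions, columns=config.regions
            )
            stars = corr.astype(object).copy()
            for fit in fits:
                ra, rb = fit.spec.region_a, fit.spec.region_b
                corr.loc[ra, rb] = corr.loc[rb, ra] = fit.rho_ss_median
                stars.loc[ra, rb] = stars.loc[rb, ra] = fit.reliability
            save(corr, "slope_correlations.tsv")
            save(stars, "slope_correlation_stars.tsv")
            finish_stage(stage)

            if config.run_pca:
                stage = "pca"
                matrix = build_slope_matrix(fits)
                matrix = adjust_covariates(matrix, cohort)
                pca = pca_slopes(matrix)
                save(matrix.values, "slope_matrix.tsv")
                save(pca.loadings, "pca_loadings.tsv")
                save(
                    pd.DataFrame(
                        {
                            "eigenvalue": pca.eigenvalues,
                            "explained": pca.explained,
                            "cumulative": pca.cumulative,
                        },
                        index=pca.loadings.columns,
                    ),
                    "pca_explained.tsv",
                )
                save(pca.scores, "pca_scores.tsv")
                finish_stage(stage)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc, manifest) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
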