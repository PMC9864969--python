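"""End-to-end pipeline: synthetic panel (or provided tables) -> preprocess ->
item TIs -> location-scale fits -> person components -> cross-sectional
association -> lagged analysis, with a reproducibility manifest.

One master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master).spawn``, so each stage is individually
reproducible and two runs with the same config produce identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlate, moderated_regression, regress_components
from .lagged import (assign_lag_bins, fit_per_survey_components,
                     lag_moderator_regression, max_stable_lag)
from .location_scale import (LocationScaleSpec, extract_person_components,
                             fit_expanded_location_scale, fit_location_scale)
from .preprocess import preprocess
from .report import lag_markdown, plot_lag_coefficients, regression_markdown
from .synthetic import PanelConfig, generate_panel, read_panel, write_panel
from .time_intensity import estimate_time_intensities

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]


@dataclass
class RunConfig:
    """Pipeline configuration; either a synthetic panel config or a directory
    of input tables (as written by ``write_panel``)."""

    seed: int = 0
    output_dir: str = "rtscale_out"
    synthetic: dict | None = None
    input_dir: str | None = None
    min_completion: float = 0.75
    trim_percentile: float = 0.99
    min_surveys: int = 5
    reference_seconds: float = 10.0
    ti_method: str = "mcmc"
    ti_iterations: int = 1500
    ti_burn_in: int = 500
    chains: int = 2
    iterations: int = 2000
    burn_in: int = 800
    age_cut: float = 40.0
    bin_width_years: float = 0.5
    max_lag_years: float = 6.5
    per_survey_min_items: int = 10
    per_survey_iterations: int = 1200
    per_survey_burn_in: int = 500
    run_lagged: bool = True
    run_association: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("config needs either 'synthetic' or 'input_dir'")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def stage_seeds(master: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    names = ["panel", "ti", "fit_ls", "fit_xls", "per_survey"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {nm: int(ch.generate_state(1)[0] % (2 ** 31))
            for nm, ch in zip(names, children)}


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.10g").encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk).

    Artifacts: clean_records.csv, ti.csv, fit_{ls,xls}.json, components.csv,
    association.json/.md, lag_bins.csv, lag_results.json/.md, lag_plot.png,
    manifest.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "rtscale_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
        "hashes": {},
    }
    stage = "load"
    try:
        if config.synthetic is not None:
            pcfg = PanelConfig.from_dict({**config.synthetic,
                                          "seed": seeds["panel"]})
            panel = generate_panel(pcfg)
            write_panel(panel, out / "panel")
        else:
            panel = read_panel(config.input_dir)
        manifest["stages"]["load"] = {"n_records": len(panel.rt_records)}

        stage = "preprocess"
        clean, rep = preprocess(
            panel.rt_records, panel.items,
            min_completion=config.min_completion,
            trim_percentile=config.trim_percentile,
            min_surveys=config.min_surveys)
        clean.to_csv(out / "clean_records.csv", index=False)
        manifest["stages"]["preprocess"] = rep.as_dict()
        manifest["hashes"]["clean_records"] = _hash_frame(
            clean[["person_id", "item_id", "rt_seconds", "log_rt"]])

        stage = "time_intensity"
        ti_fit = estimate_time_intensities(
            clean, method=config.ti_method,
            reference_seconds=config.reference_seconds,
            iterations=config.ti_iterations, burn_in=config.ti_burn_in,
            seed=seeds["ti"])
        ti_fit.ti.to_csv(out / "ti.csv", index=False)
        manifest["stages"]["time_intensity"] = {
            "mu": ti_fit.mu, "sigma_q2": ti_fit.sigma_q2,
            "method": ti_fit.method}
        manifest["hashes"]["ti"] = _hash_frame(ti_fit.ti)

        stage = "location_scale"
        spec_ls = LocationScaleSpec(chains=config.chains,
                                    iterations=config.iterations,
                                    burn_in=config.burn_in,
                                    seed=seeds["fit_ls"])
        fit_ls = fit_location_scale(clean, spec_ls)
        (out / "fit_ls.json").write_text(json.dumps(fit_ls.summary(), indent=2))

        spec_xls = LocationScaleSpec(chains=config.chains,
                                     iterations=config.iterations,
                                     burn_in=config.burn_in,
                                     seed=seeds["fit_xls"])
        fit_xls = fit_expanded_location_scale(clean, ti_fit.ti, spec_xls)
        (out / "fit_xls.json").write_text(json.dumps(fit_xls.summary(), indent=2))
        components = extract_person_components(fit_xls)
        components.to_csv(out / "components.csv", index=False)
        manifest["stages"]["location_scale"] = {
            "ls": fit_ls.summary(), "xls": fit_xls.summary()}
        manifest["hashes"]["components"] = _hash_frame(components)

        if config.run_association:
            stage = "association"
            corr = correlate(components, panel.cognitive_scores)
            reg = regress_components(panel.cognitive_scores, components)
            reg_cov = regress_components(
                panel.cognitive_scores, components,
                covariates=panel.demographics[
                    ["person_id", "age", "gender", "race_ethnicity",
                     "education", "income"]])
            mod = moderated_regression(panel.cognitive_scores, components,
                                       panel.demographics, cut=config.age_cut)
            assoc = {
                "correlations": corr.to_dict(orient="records"),
                "regression": reg.as_dict(),
                "regression_with_covariates": reg_cov.as_dict(),
                "age_moderation": mod.as_dict(),
            }
            (out / "association.json").write_text(json.dumps(assoc, indent=2))
            md = (regression_markdown(reg, "Without demographic covariates")
                  + "\n"
                  + regression_markdown(reg_cov, "With demographic covariates"))
            (out / "association.md").write_text(md)
            manifest["stages"]["association"] = {
                "R2": reg.r2, "R2_with_covariates": reg_cov.r2}

        if config.run_lagged:
            stage = "lagged"
            spec_ps = LocationScaleSpec(
                chains=config.chains,
                iterations=config.per_survey_iterations,
                burn_in=config.per_survey_burn_in,
                seed=seeds["per_survey"])
            per_survey, skipped = fit_per_survey_components(
                clean, ti_fit.ti, spec_ps,
                min_items=config.per_survey_min_items)
            bins = assign_lag_bins(per_survey, panel.cognitive_scores,
                                   bin_width_years=config.bin_width_years,
                                   max_lag_years=config.max_lag_years)
            bins.to_csv(out / "lag_bins.csv", index=False)
            lag_res = lag_moderator_regression(
                bins, panel.cognitive_scores,
                bin_width_years=config.bin_width_years)
            stable = max_stable_lag(lag_res,
                                    bin_width_years=config.bin_width_years)
            lag_json = {"result": lag_res.as_dict(),
                        "max_stable_lag_years": stable,
                        "skipped_surveys": skipped}
            (out / "lag_results.json").write_text(json.dumps(lag_json, indent=2))
            (out / "lag_results.md").write_text(lag_markdown(lag_res, stable))
            if config.make_plots:
                plot_lag_coefficients(lag_res, out / "lag_plot.png")
            manifest["stages"]["lagged"] = {
                "n_bins": len(lag_res.bins),
                "max_stable_lag_years": stable,
                "n_skipped_surveys": len(skipped)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest["result_hash"] = hashlib.sha256(
        json.dumps(manifest["hashes"], sort_keys=True).encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
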