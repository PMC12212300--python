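"""End-to-end orchestration: config, logging, run manifest.

The full run executes harmonize -> eligibility filter -> three GLMM fits ->
census prediction (+ need-satisfied) -> direct estimates and weight
calibration per indicator -> benchmarked domain estimates -> joint
parametric-bootstrap MSE, and writes one tidy estimates table with a row
per indicator x ethnic group x state, plus per-stage artifacts and a run
manifest sufficient to reproduce the outputs bit-for-bit (config hash,
seed, row counts; no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .benchmarking import (benchmarked_domain_estimates, build_constraints,
                           calibrate_weights, default_levels)
from .census_prediction import predict_all, write_predictions
from .core_data import (INDICATORS, MODELLED_INDICATORS, Codebook,
                        filter_eligible, harmonize, load_harmonization_maps,
                        validate_microdata)
from .model_fit import fit_glmm
from .mse_bootstrap import bootstrap_mse_all

logger = logging.getLogger("ethnosae")


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n- " + "\n- ".join(self.errors))


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    survey_path: str
    census_path: str
    output_dir: str
    harmonization_maps: str | None = None
    indicators: tuple[str, ...] = INDICATORS
    levels: tuple[str, ...] | None = None
    calibration_tol: float = 1e-8
    calibration_max_iter: int = 1000
    weight_bounds: tuple[float, float] = (0.2, 5.0)
    bootstrap_B: int = 200
    seed: int = 0
    n_states: int = 33
    weighted_fit: bool = False
    benchmark_in_bootstrap: bool = False
    ns_aggregation: str = "mean_of_ratios"
    exclusive_unmet: bool = True
    drop_missing: bool = False
    codebook: Codebook = field(default_factory=Codebook)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["codebook"] = list(self.codebook.terms)
        s = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(s.encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config, reporting all errors at once."""
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as e:
        raise ConfigError([f"cannot read config: {e}"]) from e
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])

    known = {f.name for f in dataclasses.fields(RunConfig)} - {"codebook"}
    for k in raw:
        if k not in known:
            errors.append(f"unknown config key {k!r}")
    for k in ("survey_path", "census_path", "output_dir"):
        if k not in raw:
            errors.append(f"missing required key {k!r}")
    for k in ("survey_path", "census_path", "harmonization_maps"):
        v = raw.get(k)
        if v is not None and not Path(v).exists():
            errors.append(f"{k}: path {v!r} does not exist")
    B = raw.get("bootstrap_B", 200)
    if not isinstance(B, int) or B < 2:
        errors.append(f"bootstrap_B must be an integer >= 2, got {B!r}")
    if raw.get("ns_aggregation", "mean_of_ratios") not in (
            "mean_of_ratios", "ratio_of_means"):
        errors.append("ns_aggregation must be 'mean_of_ratios' or "
                      "'ratio_of_means'")
    tol = raw.get("calibration_tol", 1e-8)
    if not (isinstance(tol, (int, float)) and tol > 0):
        errors.append("calibration_tol must be positive")
    bounds = raw.get("weight_bounds", (0.2, 5.0))
    if not (len(bounds) == 2 and 0 < bounds[0] <= 1 <= bounds[1]):
        errors.append("weight_bounds must satisfy 0 < lo <= 1 <= hi")
    inds = raw.get("indicators", list(INDICATORS))
    for ind in inds:
        if ind not in INDICATORS:
            errors.append(f"unknown indicator {ind!r}")
    if errors:
        raise ConfigError(errors)

    kwargs = {k: raw[k] for k in known if k in raw}
    kwargs["indicators"] = tuple(inds)
    if "levels" in kwargs and kwargs["levels"] is not None:
        kwargs["levels"] = tuple(kwargs["levels"])
    if "weight_bounds" in kwargs:
        kwargs["weight_bounds"] = tuple(kwargs["weight_bounds"])
    return RunConfig(**kwargs)


class _RunLog:
    """Structured JSONL event log with a human-readable mirror."""

    def __init__(self, path: Path):
        self.path = path
        self.events: list[dict] = []

    def event(self, stage: str, **fields):
        rec = {"stage": stage, **fields}
        self.events.append(rec)
        logger.info("stage %s: %s", stage,
                    ", ".join(f"{k}={v}" for k, v in fields.items()))
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the five-step pipeline and write all artifacts.

    Returns the final estimates table (indicator, ethnic_group, state,
    estimate, mse, rrmse_pct).  Any stage failure aborts with the stage
    name; artifacts of completed stages remain on disk for inspection.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logpath = out / "log.jsonl"
    logpath.unlink(missing_ok=True)
    runlog = _RunLog(logpath)
    counts: dict[str, int] = {}

    stage = "load_harmonize"
    try:
        maps = (load_harmonization_maps(config.harmonization_maps)
                if config.harmonization_maps else [])
        survey_raw = pd.read_csv(config.survey_path)
        census_raw = pd.read_csv(config.census_path)
        counts["survey_raw"] = len(survey_raw)
        counts["census_raw"] = len(census_raw)
        survey_raw = harmonize(survey_raw, maps, "survey")
        census_raw = harmonize(census_raw, maps, "census")
        survey_raw = filter_eligible(survey_raw)
        census_raw = filter_eligible(census_raw)
        survey = validate_microdata(survey_raw, "survey",
                                    n_states=config.n_states,
                                    exclusive_unmet=config.exclusive_unmet,
                                    drop_missing=config.drop_missing)
        census = validate_microdata(census_raw, "census",
                                    n_states=config.n_states,
                                    drop_missing=config.drop_missing)
        counts["survey_eligible"] = len(survey)
        counts["census_eligible"] = len(census)
        runlog.event(stage, survey_rows=len(survey), census_rows=len(census))
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "fit"
    try:
        models = {}
        for ind in MODELLED_INDICATORS:
            m = fit_glmm(survey, ind, config.codebook,
                         weighted=config.weighted_fit)
            m.to_json(out / f"model_{ind}.json")
            models[ind] = m
            runlog.event(stage, indicator=ind, sigma_v=m.sigma_v,
                         loglik=m.loglik, converged=m.converged)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "predict"
    try:
        predictions = predict_all(models, census)
        write_predictions(predictions, out / "predictions.csv")
        runlog.event(stage, rows=len(predictions),
                     **predictions.attrs.get("diagnostics", {}))
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "benchmark"
    try:
        levels = (list(config.levels) if config.levels
                  else default_levels(sorted(census["state"].unique())))
        from .benchmarking import PREDICTION_COLUMN
        estimates = []
        for ind in config.indicators:
            cons = build_constraints(survey, predictions, census, ind,
                                     levels)
            sol = calibrate_weights(
                predictions[PREDICTION_COLUMN[ind]].to_numpy(), cons,
                tol=config.calibration_tol,
                max_iter=config.calibration_max_iter,
                bounds=config.weight_bounds)
            sol.to_csv(out / f"weights_{ind}.csv", ids=predictions["id"])
            sol.residual_report(out / f"residuals_{ind}.json")
            est = benchmarked_domain_estimates(
                predictions, sol, ind, ns_aggregation=config.ns_aggregation)
            estimates.append(est)
            runlog.event(stage, indicator=ind, converged=sol.converged,
                         iterations=sol.iterations,
                         max_residual=max(sol.residuals.values())
                         if sol.residuals else 0.0)
        estimates = pd.concat(estimates, ignore_index=True)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "mse"
    try:
        mse = bootstrap_mse_all(models, survey, census, B=config.bootstrap_B,
                                seed=config.seed,
                                benchmark=config.benchmark_in_bootstrap,
                                ns_aggregation=config.ns_aggregation)
        runlog.event(stage, B=config.bootstrap_B,
                     B_effective=int(mse["B_effective"].iloc[0]))
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "assemble"
    try:
        final = estimates.merge(
            mse[["indicator", "ethnic_group", "state", "mse"]],
            on=["indicator", "ethnic_group", "state"], how="left")
        final["rrmse_pct"] = 100 * (final["mse"] ** 0.5) / final["estimate"]
        final["rel_mse_pct"] = 100 * final["mse"] / final["estimate"]
        final = final[final["indicator"].isin(config.indicators)]
        final = final.sort_values(["indicator", "ethnic_group", "state"])
        final = final[["indicator", "ethnic_group", "state", "estimate",
                       "mse", "rrmse_pct", "rel_mse_pct", "n"]]
        final.to_csv(out / "estimates.csv", index=False)

        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "row_counts": counts,
            "n_domains": int(estimates.groupby(
                ["ethnic_group", "state"], observed=True).ngroups),
            "outputs": sorted(p.name for p in out.iterdir()
                              if p.name != "manifest.json"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        runlog.event(stage, rows=len(final))
    except Exception as e:
        raise PipelineError(stage, e) from e

    return final.reset_index(drop=True)
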