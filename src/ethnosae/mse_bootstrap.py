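"""Parametric-bootstrap MSE for the domain estimates.

The unit-level parametric bootstrap: for b = 1..B, draw fresh domain
intercepts v* ~ N(0, sigma_hat^2), generate Bernoulli outcomes on both the
survey and the census rows from logistic(x' beta_hat + v*), take the
bootstrap-true domain proportion from the realized census outcomes, refit
the model on the bootstrap survey, re-predict and re-aggregate the domain
estimate, and average the squared deviations:

    MSE_d = mean_b (estimate*_{d,b} - truth*_{d,b})^2.

By default the bootstrap measures the model-based estimator (no
recalibration inside the loop); ``benchmark=True`` re-runs the benchmarking
weight calibration in every replicate to measure the benchmarked estimator
instead, at roughly four times the cost.  Replicates are generated from
independent seed substreams, so results do not depend on execution order or
degree of parallelism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .benchmarking import build_constraints, calibrate_weights
from .census_prediction import need_satisfied, predict_all, predict_individual
from .core_data import (MODELLED_INDICATORS, OUTCOME_FOR_INDICATOR,
                        design_matrix, domain_labels)
from .model_fit import FittedModel, SeparationError, fit_glmm

logger = logging.getLogger("ethnosae")


@dataclass
class MseResult:
    domain: str                 # "ethnic|state"
    indicator: str
    estimate: float
    mse: float
    B_effective: int
    seed: int


def relative_rmse(mse, estimate: float) -> float:
    """Root-MSE relative to the point estimate, sqrt(mse)/estimate.

    Reported as a percentage in output tables; the companion reading
    mse/estimate is emitted alongside it in the results CSV.
    """
    m = mse.mse if isinstance(mse, MseResult) else float(mse)
    if estimate <= 0:
        raise ValueError("estimate must be positive")
    if m < 0:
        raise ValueError("mse must be nonnegative")
    return math.sqrt(m) / estimate


def _domain_means(values: np.ndarray, dom: np.ndarray, keys: np.ndarray,
                  weights: np.ndarray | None = None) -> np.ndarray:
    idx = {k: j for j, k in enumerate(keys)}
    g = np.array([idx[d] for d in dom])
    w = np.ones(len(values)) if weights is None else weights
    num = np.bincount(g, weights=w * values, minlength=len(keys))
    den = np.bincount(g, weights=w, minlength=len(keys))
    with np.errstate(invalid="ignore"):
        return num / den


def bootstrap_mse(model: FittedModel, survey: pd.DataFrame,
                  census: pd.DataFrame, B: int = 200, seed: int = 0, *,
                  benchmark: bool = False, fit_tol: float = 1e-6,
                  return_replicates: bool = False):
    """Parametric-bootstrap MSE of one indicator's domain estimates.

    Replicates whose refit does not converge are dropped and counted in
    ``B_effective``; fewer than B/2 surviving replicates is a hard error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not model.converged:
        raise ValueError("bootstrap_mse requires a converged model")

    Xs, _ = design_matrix(survey, model.codebook)
    Xc, _ = design_matrix(census, model.codebook)
    eta_s = Xs @ model.beta
    eta_c = Xc @ model.beta
    dom_s = domain_labels(survey).to_numpy()
    dom_c = domain_labels(census).to_numpy()
    keys = np.unique(np.concatenate([dom_s, dom_c]))
    census_keys = np.unique(dom_c)
    gi_s = np.searchsorted(keys, dom_s)
    gi_c = np.searchsorted(keys, dom_c)
    ycol = OUTCOME_FOR_INDICATOR[model.indicator]
    warm = (model.beta, math.log(max(model.sigma_v, 0.05)))

    # point estimate from the original fit
    p_orig = predict_individual(model, census)
    est0 = _domain_means(p_orig, dom_c, census_keys)

    substreams = np.random.SeedSequence(seed).spawn(B)
    sq_err = np.zeros(len(census_keys))
    replicate_sq: list[np.ndarray] = []
    B_eff = 0
    boot_survey = survey.copy()
    for ss in substreams:
        rng = np.random.default_rng(ss)
        v_star = rng.normal(0.0, model.sigma_v, size=len(keys))
        ys = (rng.random(len(survey)) < expit(eta_s + v_star[gi_s]))
        yc = (rng.random(len(census)) < expit(eta_c + v_star[gi_c]))
        truth = _domain_means(yc.astype(float), dom_c, census_keys)
        boot_survey[ycol] = ys.astype(np.int8)
        try:
            refit = fit_glmm(boot_survey, model.indicator, model.codebook,
                             init=warm, tol=fit_tol, compute_se=False)
        except (SeparationError, np.linalg.LinAlgError):
            continue
        if not refit.converged:
            continue
        p_star = predict_individual(refit, census)
        if benchmark:
            cons = build_constraints(boot_survey,
                                     _pred_frame(census, model.indicator,
                                                 p_star),
                                     census, model.indicator)
            sol = calibrate_weights(p_star, cons)
            est = _domain_means(p_star, dom_c, census_keys, sol.weights)
        else:
            est = _domain_means(p_star, dom_c, census_keys)
        err2 = (est - truth) ** 2
        sq_err += err2
        if return_replicates:
            replicate_sq.append(err2)
        B_eff += 1

    if B_eff < B / 2:
        raise RuntimeError(
            f"bootstrap_mse: only {B_eff}/{B} replicates converged")
    if B_eff < B:
        logger.warning("bootstrap_mse(%s): dropped %d/%d non-convergent "
                       "replicates", model.indicator, B - B_eff, B)
    mse = sq_err / B_eff
    results = [MseResult(domain=str(k), indicator=model.indicator,
                         estimate=float(e), mse=float(m), B_effective=B_eff,
                         seed=seed)
               for k, e, m in zip(census_keys, est0, mse)]
    if return_replicates:
        return results, np.array(replicate_sq)
    return results


def _pred_frame(census: pd.DataFrame, indicator: str, p: np.ndarray
                ) -> pd.DataFrame:
    from .benchmarking import PREDICTION_COLUMN
    out = census.loc[:, ["id", "ethnic_group", "state"]].copy()
    out[PREDICTION_COLUMN[indicator]] = p
    return out


def bootstrap_mse_all(models: Mapping[str, FittedModel], survey: pd.DataFrame,
                      census: pd.DataFrame, B: int = 200, seed: int = 0, *,
                      benchmark: bool = False, fit_tol: float = 1e-6,
                      ns_aggregation: str = "mean_of_ratios"
                      ) -> pd.DataFrame:
    """Joint parametric bootstrap covering all four indicators.

    Outcomes are generated hierarchically from the three fitted models (the
    same construction as the synthetic generator) so that the derived
    need-satisfied indicator has a coherent bootstrap truth: the ratio of
    realized census domain means.  Returns a tidy frame with one row per
    indicator x domain.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    for ind in MODELLED_INDICATORS:
        if not models[ind].converged:
            raise ValueError(f"model {ind!r} did not converge")

    cb = models["use_any"].codebook
    Xs, _ = design_matrix(survey, cb)
    Xc, _ = design_matrix(census, cb)
    dom_s = domain_labels(survey).to_numpy()
    dom_c = domain_labels(census).to_numpy()
    keys = np.unique(np.concatenate([dom_s, dom_c]))
    census_keys = np.unique(dom_c)
    gi_s = np.searchsorted(keys, dom_s)
    gi_c = np.searchsorted(keys, dom_c)
    eta_s = {ind: Xs @ models[ind].beta for ind in MODELLED_INDICATORS}
    eta_c = {ind: Xc @ models[ind].beta for ind in MODELLED_INDICATORS}
    warm = {ind: (models[ind].beta,
                  math.log(max(models[ind].sigma_v, 0.05)))
            for ind in MODELLED_INDICATORS}

    def hierarchical_outcomes(rng, eta, g, v_star, n):
        p = {ind: expit(eta[ind] + v_star[ind][g])
             for ind in MODELLED_INDICATORS}
        with np.errstate(divide="ignore", invalid="ignore"):
            pm = np.where(p["use_any"] > 0,
                          np.minimum(p["use_modern"] / p["use_any"], 1), 0)
            pu = np.where(p["use_any"] < 1,
                          np.minimum(p["unmet"] / (1 - p["use_any"]), 1), 0)
        y_any = (rng.random(n) < p["use_any"]).astype(np.int8)
        y_mod = (y_any & (rng.random(n) < pm)).astype(np.int8)
        y_un = ((1 - y_any) & (rng.random(n) < pu)).astype(np.int8)
        return {"use_any": y_any, "use_modern": y_mod, "unmet": y_un}

    point = predict_all(models, census)
    from .benchmarking import PREDICTION_COLUMN
    est0 = {ind: _domain_means(point[PREDICTION_COLUMN[ind]].to_numpy(),
                               dom_c, census_keys)
            for ind in ("use_any", "use_modern", "unmet", "need_satisfied")}

    sq = {ind: np.zeros(len(census_keys))
          for ind in ("use_any", "use_modern", "unmet", "need_satisfied")}
    B_eff = 0
    boot_survey = survey.copy()
    for ss in np.random.SeedSequence(seed).spawn(B):
        rng = np.random.default_rng(ss)
        v_star = {ind: rng.normal(0.0, models[ind].sigma_v, size=len(keys))
                  for ind in MODELLED_INDICATORS}
        ys = hierarchical_outcomes(rng, eta_s, gi_s, v_star, len(survey))
        yc = hierarchical_outcomes(rng, eta_c, gi_c, v_star, len(census))

        t = {ind: _domain_means(yc[ind].astype(float), dom_c, census_keys)
             for ind in MODELLED_INDICATORS}
        denom = t["use_any"] + t["unmet"]
        with np.errstate(divide="ignore", invalid="ignore"):
            t["need_satisfied"] = np.where(denom > 0,
                                           t["use_modern"] / denom, np.nan)

        refits = {}
        ok = True
        for ind in MODELLED_INDICATORS:
            boot_survey[OUTCOME_FOR_INDICATOR[ind]] = ys[ind]
        for ind in MODELLED_INDICATORS:
            try:
                m = fit_glmm(boot_survey, ind, cb, init=warm[ind],
                             tol=fit_tol, compute_se=False)
            except (SeparationError, np.linalg.LinAlgError):
                ok = False
                break
            if not m.converged:
                ok = False
                break
            refits[ind] = m
        if not ok:
            continue

        p_star = {ind: predict_individual(refits[ind], census)
                  for ind in MODELLED_INDICATORS}
        p_star["need_satisfied"] = need_satisfied(
            p_star["use_modern"], p_star["use_any"], p_star["unmet"])

        for ind in ("use_any", "use_modern", "unmet", "need_satisfied"):
            if benchmark:
                pred = _pred_frame(census, ind, p_star[ind])
                cons = build_constraints(boot_survey, pred, census, ind)
                sol = calibrate_weights(p_star[ind], cons)
                est = _domain_means(p_star[ind], dom_c, census_keys,
                                    sol.weights)
            else:
                est = _domain_means(p_star[ind], dom_c, census_keys)
            sq[ind] += np.where(np.isfinite(t[ind]),
                                (est - t[ind]) ** 2, 0.0)
        B_eff += 1

    if B_eff < B / 2:
        raise RuntimeError(
            f"bootstrap_mse_all: only {B_eff}/{B} replicates converged")

    rows = []
    for ind in ("use_any", "use_modern", "unmet", "need_satisfied"):
        for j, k in enumerate(census_keys):
            eth, st = str(k).split("|")
            est = float(est0[ind][j])
            mse = float(sq[ind][j] / B_eff)
            rows.append({
                "indicator": ind, "ethnic_group": eth, "state": int(st),
                "estimate": est, "mse": mse,
                "rrmse_pct": 100 * relative_rmse(mse, est) if est > 0
                else float("nan"),
                "rel_mse_pct": 100 * mse / est if est > 0 else float("nan"),
                "B_effective": B_eff, "seed": seed,
            })
    return pd.DataFrame(rows)


def results_table(results: Sequence[MseResult]) -> pd.DataFrame:
    """Tidy CSV-ready table for single-indicator bootstrap results."""
    rows = []
    for r in results:
        eth, st = r.domain.split("|")
        rows.append({
            "indicator": r.indicator, "ethnic_group": eth, "state": int(st),
            "estimate": r.estimate, "mse": r.mse,
            "rrmse_pct": 100 * relative_rmse(r, r.estimate)
            if r.estimate > 0 else float("nan"),
            "rel_mse_pct": 100 * r.mse / r.estimate
            if r.estimate > 0 else float("nan"),
            "B_effective": r.B_effective, "seed": r.seed,
        })
    return pd.DataFrame(rows)
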