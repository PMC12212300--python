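"""Benchmarking: direct survey estimates, adjustment ratios, raking weights.

Model-based census estimates are made consistent with the design-based
survey estimates at the levels where the survey is trusted (national, each
state, rural, urban).  For each level j the survey gives a Hajek direct
estimate D_{A,j}; the census unadjusted mean Y_{A,j} of the predicted
probabilities gives the adjustment ratio R_j = D_{A,j} / Y_{A,j}.  Because
the R_j differ across overlapping levels, a single census weight set is
found by raking (iterative proportional updating): cycling over the levels,
each constraint is met exactly by a multiplicative exponential tilt
w_i <- w_i * exp(lambda (p_i - D_j)) on the level's members — the
chi-square-minimal adjustment for a Hajek ratio constraint — until every
constraint's weighted mean reproduces D_j within tolerance.  One weight set
is produced per indicator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_data import INDICATORS

logger = logging.getLogger("ethnosae")

#: survey outcome and census prediction columns per indicator
_SURVEY_COLUMN = {"use_any": "y_use_any", "use_modern": "y_use_modern",
                  "unmet": "y_unmet"}
PREDICTION_COLUMN = {"use_any": "p_use_any", "use_modern": "p_use_modern",
                     "unmet": "p_unmet", "need_satisfied": "p_need_satisfied"}


class InfeasibleConstraintError(ValueError):
    pass


def level_mask(df: pd.DataFrame, level: str) -> np.ndarray:
    """Row membership for a benchmark level id.

    Levels: ``national`` (all rows), ``state:<code>``, ``rural``, ``urban``.
    """
    if level == "national":
        return np.ones(len(df), dtype=bool)
    if level in ("rural", "urban"):
        return (df["urbanicity"].astype(str) == level).to_numpy()
    if level.startswith("state:"):
        return (df["state"].astype(int) == int(level.split(":", 1)[1])).to_numpy()
    raise ValueError(f"unknown benchmark level {level!r}")


def default_levels(states: Sequence[int]) -> list[str]:
    """States first, then rural/urban, national last in each raking sweep
    (the national constraint is near-redundant given the states)."""
    return [f"state:{d}" for d in sorted(states)] + ["rural", "urban",
                                                     "national"]


def hajek_mean(y: np.ndarray, w: np.ndarray) -> float:
    """Weighted ratio mean sum(w y)/sum(w), invariant to weight rescaling."""
    sw = float(np.sum(w))
    if sw <= 0:
        raise ValueError("weights sum to zero")
    return float(np.sum(w * y) / sw)


def direct_estimates(survey: pd.DataFrame, indicator: str,
                     levels: Sequence[str]) -> dict[str, float]:
    """Design-based Hajek estimates of the indicator at each level.

    For the derived need-satisfied indicator the direct estimate is the
    weighted ratio sum(w y_modern) / (sum(w y_any) + sum(w y_unmet)).
    Empty levels are reported as NaN with a warning.
    """
    w_all = survey["weight"].to_numpy().astype(float)
    out: dict[str, float] = {}
    for lev in levels:
        m = level_mask(survey, lev)
        if not m.any():
            logger.warning("direct_estimates(%s): level %r has no survey "
                           "rows; estimate undefined", indicator, lev)
            out[lev] = float("nan")
            continue
        w = w_all[m]
        if indicator == "need_satisfied":
            num = float(np.sum(w * survey.loc[m, "y_use_modern"]))
            den = float(np.sum(w * (survey.loc[m, "y_use_any"]
                                    + survey.loc[m, "y_unmet"])))
            out[lev] = num / den if den > 0 else float("nan")
        else:
            y = survey.loc[m, _SURVEY_COLUMN[indicator]].to_numpy()
            out[lev] = hajek_mean(y, w)
    return out


def ratio_adjust(D: float, Y: float) -> float:
    """Adjustment ratio R = D / Y of direct to census estimate."""
    if Y <= 0:
        raise ZeroDivisionError("census-level estimate Y must be positive")
    return D / Y


@dataclass
class LevelConstraint:
    """One benchmark level: its direct estimate, census mean and ratio."""
    level: str
    indicator: str
    D: float                      # survey direct estimate
    Y: float                      # census unadjusted mean of predictions
    R: float                      # D / Y
    mask: np.ndarray = field(repr=False)


def build_constraints(survey: pd.DataFrame, predictions: pd.DataFrame,
                      census: pd.DataFrame, indicator: str,
                      levels: Sequence[str] | None = None
                      ) -> list[LevelConstraint]:
    """Assemble the benchmark constraints for one indicator.

    ``census`` supplies level membership for the prediction rows (same row
    order as ``predictions``).
    """
    if levels is None:
        levels = default_levels(sorted(census["state"].unique()))
    p = predictions[PREDICTION_COLUMN[indicator]].to_numpy()
    D = direct_estimates(survey, indicator, levels)
    out = []
    for lev in levels:
        m = level_mask(census, lev)
        if not m.any() or not np.isfinite(D[lev]):
            logger.warning("build_constraints(%s): skipping level %r "
                           "(empty or undefined direct estimate)",
                           indicator, lev)
            continue
        Y = float(p[m].mean())
        out.append(LevelConstraint(level=lev, indicator=indicator,
                                   D=D[lev], Y=Y, R=ratio_adjust(D[lev], Y),
                                   mask=m))
    return out


@dataclass
class WeightSolution:
    weights: np.ndarray
    residuals: dict[str, float]
    iterations: int
    converged: bool
    n_bound_hits: int = 0
    infeasible: list[str] = field(default_factory=list)

    def to_csv(self, path, ids=None) -> None:
        pd.DataFrame({"id": ids if ids is not None
                      else np.arange(len(self.weights)),
                      "weight": self.weights}).to_csv(path, index=False)

    def residual_report(self, path=None) -> str:
        d = {"residuals": self.residuals, "iterations": self.iterations,
             "converged": self.converged, "n_bound_hits": self.n_bound_hits,
             "infeasible": self.infeasible}
        s = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _solve_tilt(w, c):
    """Solve sum(w exp(lambda c) c) = 0 for lambda (f is increasing)."""
    f = lambda lam: float(np.sum(w * np.exp(np.clip(lam * c, -200, 200)) * c))
    lam = 0.0
    f0 = f(0.0)
    if f0 == 0.0:
        return 0.0
    # Newton with brentq fallback
    for _ in range(50):
        fp = float(np.sum(w * np.exp(np.clip(lam * c, -200, 200)) * c * c))
        if fp <= 0:
            break
        step = -f(lam) / fp
        lam_new = lam + step
        if abs(step) < 1e-14 * (1 + abs(lam)):
            return lam_new
        lam = lam_new
        if abs(lam) > 1e3:
            break
    lo, hi = -1.0, 1.0
    for _ in range(80):
        if f(lo) < 0 < f(hi):
            return brentq(f, lo, hi, xtol=1e-14)
        lo *= 2
        hi *= 2
    raise InfeasibleConstraintError("tilt root bracketing failed")


def calibrate_weights(predictions: np.ndarray,
                      constraints: Sequence[LevelConstraint],
                      tol: float = 1e-8, max_iter: int = 1000,
                      bounds: tuple[float, float] = (0.2, 5.0)
                      ) -> WeightSolution:
    """Raking over the benchmark constraints.

    Starting from unit weights, cycles over the constraints solving each
    one's exponential tilt exactly, clipping to ``bounds`` (hits logged),
    until every constraint's Hajek mean matches its direct estimate within
    ``tol``.  An infeasible system returns a non-converged solution with a
    residual report and a warning, never silently.
    """
    p = np.asarray(predictions, dtype=float)
    w = np.ones(len(p))
    if not constraints:
        return WeightSolution(weights=w, residuals={}, iterations=0,
                              converged=True)

    infeasible: list[str] = []
    n_bound_hits = 0

    def residuals():
        return {c.level: abs(hajek_mean(p[c.mask], w[c.mask]) - c.D)
                for c in constraints}

    def clip_bounds(w):
        nonlocal n_bound_hits
        hits = (w < bounds[0]) | (w > bounds[1])
        if hits.any():
            n_bound_hits += int(hits.sum())
            logger.info("calibrate_weights: %d weights clipped to "
                        "bounds %s", int(hits.sum()), bounds)
            w = np.clip(w, bounds[0], bounds[1])
        return w

    # phase 1: cyclic raking sweeps (each constraint met exactly in turn)
    it = 0
    rake_sweeps = min(max_iter, 30)
    for it in range(1, rake_sweeps + 1):
        for c in constraints:
            cc = p[c.mask] - c.D
            if cc.min() >= 0 or cc.max() <= 0:
                if c.level not in infeasible:
                    infeasible.append(c.level)
                continue
            try:
                lam = _solve_tilt(w[c.mask], cc)
            except InfeasibleConstraintError:
                if c.level not in infeasible:
                    infeasible.append(c.level)
                continue
            w[c.mask] = w[c.mask] * np.exp(np.clip(lam * cc, -200, 200))
            w = clip_bounds(w)
        res = residuals()
        if max(res.values()) <= tol:
            return WeightSolution(weights=w, residuals=res, iterations=it,
                                  converged=True, n_bound_hits=n_bound_hits,
                                  infeasible=infeasible)

    # phase 2: joint Newton on the tilt multipliers.  Overlapping levels
    # (states vs rural/urban) make cyclic raking converge linearly with a
    # rate near one; solving all constraints simultaneously, still within
    # the exponential-tilt family, is quadratically convergent from the
    # raking warm start.
    active = [c for c in constraints if c.level not in infeasible]
    if active:
        K = len(active)
        M = np.stack([c.mask for c in active])             # K x n
        C = np.stack([(p - c.D) * c.mask for c in active])  # tilt directions

        def resid_vec(w):
            W = M @ w
            return (M * p) @ w / W - np.array([c.D for c in active])

        r = resid_vec(w)
        for _ in range(max_iter - it):
            if np.max(np.abs(r)) <= tol:
                break
            it += 1
            W = M @ w
            means = (M * p) @ w / W
            A = C * w                                       # dw/dlam rows
            J = (M * (p[None, :] - means[:, None])) @ A.T / W[:, None]
            try:
                dlam = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError:
                dlam, *_ = np.linalg.lstsq(J, -r, rcond=None)
            alpha, best = 1.0, np.max(np.abs(r))
            stepped = False
            for _ in range(30):
                w_try = clip_bounds(
                    w * np.exp(np.clip(alpha * (dlam @ C), -200, 200)))
                r_try = resid_vec(w_try)
                if np.max(np.abs(r_try)) < best:
                    w, r = w_try, r_try
                    stepped = True
                    break
                alpha *= 0.5
            if not stepped:
                break
        res = residuals()
        if max(res.values()) <= tol:
            return WeightSolution(weights=w, residuals=res, iterations=it,
                                  converged=True, n_bound_hits=n_bound_hits,
                                  infeasible=infeasible)

    res = residuals()
    logger.warning("calibrate_weights: not converged after %d sweeps; "
                   "max residual %.3g (infeasible levels: %s)",
                   max_iter, max(res.values()) if res else float("nan"),
                   infeasible)
    return WeightSolution(weights=w, residuals=res, iterations=it,
                          converged=False, n_bound_hits=n_bound_hits,
                          infeasible=infeasible)


def benchmarked_domain_estimates(predictions: pd.DataFrame,
                                 weights, indicator: str,
                                 domains: Sequence[tuple[str, int]] | None = None,
                                 ns_aggregation: str = "mean_of_ratios"
                                 ) -> pd.DataFrame:
    """Weighted domain means of the predicted probabilities.

    ``weights`` is a WeightSolution or a raw weight vector aligned with the
    prediction rows.  ``ns_aggregation`` selects how need-satisfied is
    aggregated: weighted mean of the individual ratios (default, matching
    the individual-level definition) or the ratio of aggregated means.
    Requested domains with no census rows are reported with NaN estimates.
    """
    if isinstance(weights, WeightSolution):
        if not weights.converged:
            logger.warning("benchmarked_domain_estimates: weight solution "
                           "did not converge; estimates use it anyway")
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
    if ns_aggregation not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown ns_aggregation {ns_aggregation!r}")

    df = predictions.copy()
    df["_w"] = w
    rows = []
    grouped = df.groupby(["ethnic_group", "state"], observed=True)
    seen = set()
    for (eth, st), block in grouped:
        seen.add((str(eth), int(st)))
        ww = block["_w"].to_numpy()
        if indicator == "need_satisfied" and ns_aggregation == "ratio_of_means":
            num = float(np.sum(ww * block["p_use_modern"]))
            den = float(np.sum(ww * (block["p_use_any"] + block["p_unmet"])))
            est = num / den if den > 0 else float("nan")
        else:
            est = hajek_mean(block[PREDICTION_COLUMN[indicator]].to_numpy(),
                             ww)
        rows.append({"ethnic_group": str(eth), "state": int(st),
                     "estimate": est, "n": len(block)})
    if domains is not None:
        for eth, st in domains:
            if (str(eth), int(st)) not in seen:
                logger.warning("benchmarked_domain_estimates: domain "
                               "(%s, %s) has no census rows", eth, st)
                rows.append({"ethnic_group": str(eth), "state": int(st),
                             "estimate": float("nan"), "n": 0})
    out = pd.DataFrame(rows).sort_values(["ethnic_group", "state"])
    out.insert(0, "indicator", indicator)
    return out.reset_index(drop=True)
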