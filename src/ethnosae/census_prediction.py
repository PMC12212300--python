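"""Individual-level census prediction and the need-satisfied indicator.

Each fitted survey model is carried to the census: every census woman gets
p_hat = logistic(x' beta_hat + v_hat_d) for her (ethnic group, state)
domain, with v_hat = 0 for domains the survey never observed (prediction
from fixed effects only, the conventional SAE fallback).  The fourth
indicator is derived per woman as

    p_need_satisfied = p_modern / (p_any + p_unmet),

clipped to [0, 1] with a logged count when the independently fitted models
produce a ratio above one.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import design_matrix, domain_labels
from .model_fit import FittedModel

logger = logging.getLogger("ethnosae")


class UndefinedRatioError(ZeroDivisionError):
    """need_satisfied denominator p_any + p_unmet is zero."""


def predict_individual(model: FittedModel, census: pd.DataFrame
                       ) -> np.ndarray:
    """Per-row predicted probability of the model's indicator.

    Probabilities are computed in log-odds space and transformed once, so
    extreme linear predictors saturate gracefully.  Raises if the census
    contains a categorical level the model never saw at fit time.
    """
    for col, levels in model.observed_levels.items():
        seen = set(levels)
        present = set(census[col].astype(str).unique())
        unseen = present - seen
        if unseen:
            raise ValueError(
                f"census column {col!r} has categories unseen at fit time: "
                f"{sorted(unseen)}")
    X, _ = design_matrix(census, model.codebook)
    dom = domain_labels(census).to_numpy()
    v = np.array([model.v_hat.get(d, 0.0) for d in dom])
    missing = sorted({d for d in dom if d not in model.v_hat})
    if missing:
        logger.info("predict_individual(%s): %d domains absent from the "
                    "survey use fixed-effects-only prediction: %s",
                    model.indicator, len(missing), missing)
    return expit(X @ model.beta + v)


def need_satisfied(p_modern, p_any, p_unmet):
    """Share of family-planning demand met with modern methods.

    ratio = p_modern / (p_any + p_unmet), elementwise for arrays.  A zero
    denominator raises (the caller decides exclusion); ratios above one —
    possible because the three models are fitted independently — are
    clipped to 1 with a logged count.
    """
    p_modern = np.asarray(p_modern, dtype=float)
    p_any = np.asarray(p_any, dtype=float)
    p_unmet = np.asarray(p_unmet, dtype=float)
    denom = p_any + p_unmet
    if np.any(denom == 0):
        raise UndefinedRatioError(
            "need_satisfied undefined: p_any + p_unmet = 0")
    ratio = p_modern / denom
    n_clip = int(np.sum(ratio > 1))
    if n_clip:
        logger.info("need_satisfied: clipped %d ratios above 1 "
                    "(independently fitted models disagree)", n_clip)
    ratio = np.clip(ratio, 0.0, 1.0)
    return float(ratio) if ratio.ndim == 0 else ratio


def predict_all(models: Mapping[str, FittedModel], census: pd.DataFrame
                ) -> pd.DataFrame:
    """Predictions table for all four indicators.

    Columns: id, ethnic_group, state, p_use_any, p_use_modern, p_unmet,
    p_need_satisfied.  Also attaches a ``diagnostics`` attribute with the
    fraction of rows where p_modern exceeds p_any (kept raw for the three
    modelled indicators, clipped only inside the need-satisfied ratio).
    """
    out = census.loc[:, ["id", "ethnic_group", "state"]].copy()
    out["p_use_any"] = predict_individual(models["use_any"], census)
    out["p_use_modern"] = predict_individual(models["use_modern"], census)
    out["p_unmet"] = predict_individual(models["unmet"], census)
    out["p_need_satisfied"] = need_satisfied(
        out["p_use_modern"].to_numpy(), out["p_use_any"].to_numpy(),
        out["p_unmet"].to_numpy())
    frac_violating = float(np.mean(out["p_use_modern"] > out["p_use_any"]))
    if frac_violating:
        logger.info("predict_all: p_modern > p_any for %.2f%% of census rows",
                    100 * frac_violating)
    out.attrs["diagnostics"] = {"frac_modern_gt_any": frac_violating}
    return out


def write_predictions(pred: pd.DataFrame, path) -> None:
    pred.to_csv(path, index=False)
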