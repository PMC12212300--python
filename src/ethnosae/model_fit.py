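"""Unit-level logistic mixed model: Laplace-ML fit, ICC, odds ratios.

The model for each indicator A is

    logit P(y_i = 1) = x_i' beta_A + v_{A,d(i)},    v_{A,d} ~ N(0, sigma_A^2)

with one random intercept per (ethnic group, state) domain d.  The marginal
likelihood integrates the domain intercepts out; because the random effect
is scalar per domain the integral factorizes into one-dimensional integrals,
each approximated by the Laplace method at the conditional mode:

    l_d(beta, sigma) = h_d(v_hat_d) - log sigma - 0.5 * log H_d,

where h_d is the joint log-density of the domain's data and intercept, and
H_d = sum_i mu_i + 1/sigma^2 is the negative curvature at the mode
(mu_i = p_i (1 - p_i)).  Maximization is over (beta, log sigma) with an
analytic gradient (envelope theorem for h, implicit differentiation of the
mode inside the log-determinant term), L-BFGS-B followed by Newton polish
until the gradient norm meets the tolerance.  Conditional modes v_hat are
the predicted random intercepts used for census prediction.

Survey weights are not used in fitting by default (they enter at the
benchmarking stage); ``weighted=True`` switches to a weighted
pseudo-likelihood.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .core_data import (Codebook, MODELLED_INDICATORS, OUTCOME_FOR_INDICATOR,
                        design_matrix, domain_labels)

logger = logging.getLogger("ethnosae")

_LOG_SIGMA_MIN = math.log(1e-6)
_LOG_SIGMA_MAX = math.log(50.0)


class SeparationError(ValueError):
    """A covariate perfectly separates the outcome."""


class NotFittedError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Fitted-model container
# --------------------------------------------------------------------------

@dataclass
class FittedModel:
    indicator: str
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma_v: float
    v_hat: dict[str, float]          # "ethnic|state" -> conditional mode
    loglik: float
    converged: bool
    n_obs: int
    n_domains: int
    codebook: Codebook = field(default_factory=Codebook)
    grad_norm: float = float("nan")
    n_iter: int = 0
    observed_levels: dict[str, list[str]] = field(default_factory=dict)

    def coef(self, name: str) -> float:
        try:
            return float(self.beta[self.names.index(name)])
        except ValueError:
            raise KeyError(f"unknown coefficient {name!r}") from None

    def to_json(self, path=None) -> str:
        d = {
            "indicator": self.indicator,
            "names": self.names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "sigma_v": self.sigma_v,
            "v_hat": self.v_hat,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_domains": self.n_domains,
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "codebook_terms": list(self.codebook.terms),
            "observed_levels": self.observed_levels,
        }
        s = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(indicator=d["indicator"], names=d["names"],
                   beta=np.asarray(d["beta"]), se=np.asarray(d["se"]),
                   sigma_v=d["sigma_v"], v_hat=d["v_hat"],
                   loglik=d["loglik"], converged=d["converged"],
                   n_obs=d["n_obs"], n_domains=d["n_domains"],
                   codebook=Codebook(tuple(d["codebook_terms"])),
                   grad_norm=d.get("grad_norm", float("nan")),
                   n_iter=d.get("n_iter", 0),
                   observed_levels=d.get("observed_levels", {}))


# --------------------------------------------------------------------------
# Laplace marginal likelihood
# --------------------------------------------------------------------------

def _solve_modes(eta0, y, g, G, s2, w, v):
    """Damped Newton for the per-domain conditional modes (concave in v)."""
    inv_s2 = 1.0 / s2
    for _ in range(200):
        eta = eta0 + v[g]
        p = expit(eta)
        grad = np.bincount(g, weights=w * (y - p), minlength=G) - v * inv_s2
        hess = np.bincount(g, weights=w * p * (1 - p), minlength=G) + inv_s2
        step = grad / hess
        # objective is strictly concave per domain: damp oversized steps
        step = np.clip(step, -4.0, 4.0)
        v = v + step
        if np.max(np.abs(step)) < 1e-11:
            break
    return v


def _laplace_nll(theta, X, y, g, G, w, vcache):
    """Negative Laplace marginal log-likelihood and its gradient."""
    p_dim = X.shape[1]
    beta = theta[:p_dim]
    log_sigma = theta[p_dim]
    sigma = math.exp(log_sigma)
    s2 = sigma * sigma
    inv_s2 = 1.0 / s2

    eta0 = X @ beta
    v = _solve_modes(eta0, y, g, G, s2, w, vcache.copy())
    vcache[:] = v

    eta = eta0 + v[g]
    p = expit(eta)
    mu = w * p * (1 - p)                       # working weights
    mup = mu * (1 - 2 * p)                     # d mu / d eta
    Sw = np.bincount(g, weights=mu, minlength=G)
    Swp = np.bincount(g, weights=mup, minlength=G)
    H = Sw + inv_s2

    # h(v_hat): Bernoulli log-lik plus the Gaussian exponent
    ll_bern = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    h = ll_bern - 0.5 * float(np.sum(v * v)) * inv_s2
    ll = h - G * log_sigma - 0.5 * float(np.sum(np.log(H)))

    # gradient wrt beta
    r = w * (y - p)
    g_beta = X.T @ r
    U = np.empty((G, p_dim))
    T = np.empty((G, p_dim))
    for k in range(p_dim):
        U[:, k] = np.bincount(g, weights=mu * X[:, k], minlength=G)
        T[:, k] = np.bincount(g, weights=mup * X[:, k], minlength=G)
    dv_dbeta = -U / H[:, None]
    dH_dbeta = T + Swp[:, None] * dv_dbeta
    g_beta = g_beta - 0.5 * np.sum(dH_dbeta / H[:, None], axis=0)

    # gradient wrt sigma, then chain to log sigma
    sigma3 = sigma * s2
    dv_dsigma = (2.0 * v / sigma3) / H
    dH_dsigma = Swp * dv_dsigma - 2.0 / sigma3
    dl_dsigma = (float(np.sum(v * v)) / sigma3 - G / sigma
                 - 0.5 * float(np.sum(dH_dsigma / H)))
    grad = np.empty(p_dim + 1)
    grad[:p_dim] = -g_beta
    grad[p_dim] = -dl_dsigma * sigma
    return -ll, grad


def _numeric_hessian(fun, theta, eps=1e-5):
    """Central-difference Hessian from the analytic gradient."""
    k = theta.size
    Hm = np.empty((k, k))
    for j in range(k):
        h = eps * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        _, gp = fun(tp)
        _, gm = fun(tm)
        Hm[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (Hm + Hm.T)


def _check_separation(X, names, y):
    """Error on binary covariates that perfectly split the outcome."""
    for k in range(1, X.shape[1]):
        x = X[:, k]
        vals = np.unique(x)
        if not np.all(np.isin(vals, [0.0, 1.0])) or vals.size < 2:
            continue
        y1 = y[x == 1]
        y0 = y[x == 0]
        if y1.size and y0.size and y1.min() == y1.max() \
                and y0.min() == y0.max() and y1[0] != y0[0]:
            raise SeparationError(
                f"covariate {names[k]!r} completely separates the outcome")


def _irls_logistic(X, y, w, n_iter=12, ridge=1e-8):
    """Plain-logistic IRLS starting values."""
    n, p_dim = X.shape
    beta = np.zeros(p_dim)
    ybar = min(max(float(np.average(y, weights=w)), 1e-3), 1 - 1e-3)
    beta[0] = math.log(ybar / (1 - ybar))
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = expit(eta)
        W = w * p * (1 - p) + 1e-10
        z = eta + (y - p) / (p * (1 - p) + 1e-10)
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X + ridge * np.eye(p_dim), XtW @ z)
    return beta


def fit_glmm(survey: pd.DataFrame, indicator: str,
             codebook: Codebook | None = None, *,
             groups: Sequence[str] | None = None,
             weighted: bool = False,
             tol: float = 1e-8,
             init: tuple[np.ndarray, float] | None = None,
             max_iter: int = 400,
             compute_se: bool = True) -> FittedModel:
    """Fit the Bernoulli-logit GLMM by Laplace maximum likelihood.

    Parameters
    ----------
    survey : validated survey microdata with the indicator's outcome column.
    indicator : one of ``use_any``, ``use_modern``, ``unmet``.
    groups : optional explicit cluster labels (default: ethnic|state
        domains); used e.g. by the cluster bootstrap.
    weighted : use sampling weights as a pseudo-likelihood (off by default;
        the benchmark stage, not the fit, consumes the design weights).
    tol : infinity-norm gradient tolerance reported by the converged flag.
    init : optional warm start ``(beta, log_sigma)``.

    Non-convergence is flagged on the result, never silent; complete
    separation raises :class:`SeparationError` naming the covariate.
    """
    if indicator not in MODELLED_INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    codebook = codebook or Codebook()
    X, names = design_matrix(survey, codebook)
    y = survey[OUTCOME_FOR_INDICATOR[indicator]].to_numpy().astype(float)
    if groups is None:
        groups = domain_labels(survey).to_numpy()
    else:
        groups = np.asarray(groups, dtype=object)
    keys, g = np.unique(groups, return_inverse=True)
    G = len(keys)
    w = survey["weight"].to_numpy().astype(float) if weighted \
        else np.ones(len(survey))
    if weighted:
        w = w * len(w) / w.sum()     # normalize to sum n

    _check_separation(X, names, y)

    p_dim = X.shape[1]
    vcache = np.zeros(G)
    obj = lambda th: _laplace_nll(th, X, y, g, G, w, vcache)

    if init is not None:
        beta0, ls0 = np.asarray(init[0], float).copy(), float(init[1])
    else:
        beta0 = _irls_logistic(X, y, w)
        ls0 = math.log(0.3)
    theta0 = np.concatenate([beta0, [min(max(ls0, _LOG_SIGMA_MIN),
                                         _LOG_SIGMA_MAX)]])

    bounds = [(None, None)] * p_dim + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    res = minimize(obj, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-14,
                            "gtol": min(tol, 1e-9), "maxcor": 25})
    theta = res.x
    n_iter = int(res.nit)

    def free_grad_norm(th, gr):
        gr = gr.copy()
        if th[p_dim] <= _LOG_SIGMA_MIN + 1e-9 and gr[p_dim] > 0:
            gr[p_dim] = 0.0          # pinned at the sigma -> 0 boundary
        return float(np.max(np.abs(gr)))

    # Newton polish: drive the gradient below tol
    f, gr = obj(theta)
    lam = 1e-8
    for _ in range(60):
        if free_grad_norm(theta, gr) < tol:
            break
        Hm = _numeric_hessian(obj, theta)
        at_lb = theta[p_dim] <= _LOG_SIGMA_MIN + 1e-9 and gr[p_dim] > 0
        idx = np.arange(p_dim) if at_lb else np.arange(p_dim + 1)
        sub = Hm[np.ix_(idx, idx)]
        step = np.zeros(p_dim + 1)
        try:
            step[idx] = np.linalg.solve(
                sub + lam * np.eye(idx.size), -gr[idx])
        except np.linalg.LinAlgError:
            lam *= 100
            continue
        alpha = 1.0
        improved = False
        for _ in range(40):
            cand = theta + alpha * step
            cand[p_dim] = min(max(cand[p_dim], _LOG_SIGMA_MIN),
                              _LOG_SIGMA_MAX)
            fc, gc = obj(cand)
            if fc <= f + 1e-12 * abs(f):
                theta, f, gr = cand, fc, gc
                improved = True
                break
            alpha *= 0.5
        n_iter += 1
        if improved:
            lam = max(lam * 0.3, 1e-10)
        else:
            lam *= 100
            if lam > 1e8:
                break

    grad_norm = free_grad_norm(theta, gr)
    converged = bool(grad_norm < tol)
    if not converged:
        logger.warning("fit_glmm(%s): gradient norm %.3g above tolerance "
                       "%.1g after %d iterations", indicator, grad_norm,
                       tol, n_iter)

    beta = theta[:p_dim]
    sigma = math.exp(theta[p_dim])
    if theta[p_dim] <= _LOG_SIGMA_MIN + 1e-9:
        sigma = 0.0

    # standard errors from the observed information of the Laplace objective
    se = np.full(p_dim, np.nan)
    if compute_se:
        Hm = _numeric_hessian(obj, theta)
        try:
            cov = np.linalg.inv(Hm)
            d = np.diag(cov)[:p_dim]
            if np.all(d > 0):
                se = np.sqrt(d)
            else:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            try:
                se = np.sqrt(np.diag(np.linalg.inv(Hm[:p_dim, :p_dim])))
            except np.linalg.LinAlgError:
                logger.warning("fit_glmm(%s): singular information matrix; "
                               "standard errors unavailable", indicator)

    s2 = max(sigma, 1e-6) ** 2
    v = _solve_modes(X @ beta, y, g, G, s2, w, np.zeros(G))
    if sigma == 0.0:
        v = np.zeros(G)
    v_hat = {str(k): float(vd) for k, vd in zip(keys, v)}

    observed = {}
    for col in ("age_group", "education"):
        if col in survey.columns:
            observed[col] = sorted(survey[col].astype(str).unique())

    if np.max(np.abs(beta)) > 30:
        logger.warning("fit_glmm(%s): extreme coefficient magnitude; "
                       "possible quasi-separation", indicator)

    return FittedModel(indicator=indicator, names=list(names), beta=beta,
                       se=se, sigma_v=float(sigma), v_hat=v_hat,
                       loglik=float(-f), converged=converged,
                       n_obs=len(survey), n_domains=G, codebook=codebook,
                       grad_norm=grad_norm, n_iter=n_iter,
                       observed_levels=observed)


def laplace_loglik(model: FittedModel, survey: pd.DataFrame,
                   beta=None, sigma_v=None, *, weighted: bool = False
                   ) -> float:
    """Laplace marginal log-likelihood of given parameters on ``survey``."""
    X, _ = design_matrix(survey, model.codebook)
    y = survey[OUTCOME_FOR_INDICATOR[model.indicator]].to_numpy().astype(float)
    keys, g = np.unique(domain_labels(survey).to_numpy(), return_inverse=True)
    w = survey["weight"].to_numpy().astype(float) if weighted \
        else np.ones(len(survey))
    beta = model.beta if beta is None else np.asarray(beta, float)
    sigma = model.sigma_v if sigma_v is None else float(sigma_v)
    ls = math.log(max(sigma, 1e-6))
    theta = np.concatenate([beta, [ls]])
    nll, _ = _laplace_nll(theta, X, y, g, len(keys), w, np.zeros(len(keys)))
    return -nll


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

_LATENT_VAR = math.pi ** 2 / 3.0


def icc(model) -> float:
    """Latent-scale intraclass correlation sigma^2 / (sigma^2 + pi^2/3).

    Accepts a :class:`FittedModel` or a numeric random-intercept SD.  The
    logistic residual is fixed at pi^2/3 on the latent scale, so the ICC is
    the share of latent variance attributable to between-domain differences.
    """
    sigma = model.sigma_v if isinstance(model, FittedModel) else float(model)
    s2 = sigma * sigma
    return s2 / (s2 + _LATENT_VAR)


@dataclass
class IccBootstrap:
    mean: float
    lower: float
    upper: float
    values: np.ndarray
    n_dropped: int


def icc_bootstrap_ci(survey: pd.DataFrame, indicator: str,
                     codebook: Codebook | None = None, B: int = 500,
                     seed: int = 0, **fit_kwargs) -> IccBootstrap:
    """Nonparametric cluster bootstrap CI for the ICC.

    Domains (ethnic|state clusters) are resampled with replacement B times;
    each replicate refits the GLMM with resampled clusters relabelled as
    distinct groups, and the 95% interval is the percentile interval of the
    replicate ICCs.  Non-convergent replicates are dropped and counted.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    codebook = codebook or Codebook()
    rng = np.random.default_rng(seed)
    labels = domain_labels(survey).to_numpy()
    keys = np.unique(labels)
    by_domain = {k: np.flatnonzero(labels == k) for k in keys}
    full = fit_glmm(survey, indicator, codebook, **fit_kwargs)
    warm = (full.beta, math.log(max(full.sigma_v, 0.05)))

    values = []
    dropped = 0
    for _ in range(B):
        chosen = rng.choice(keys, size=len(keys), replace=True)
        idx = np.concatenate([by_domain[k] for k in chosen])
        grp = np.repeat(np.arange(len(chosen)),
                        [len(by_domain[k]) for k in chosen])
        rep = survey.iloc[idx].reset_index(drop=True)
        try:
            m = fit_glmm(rep, indicator, codebook,
                         groups=[f"b{j}" for j in grp], init=warm,
                         **fit_kwargs)
        except (SeparationError, np.linalg.LinAlgError):
            dropped += 1
            continue
        if not m.converged:
            dropped += 1
            continue
        values.append(icc(m))
    if dropped:
        logger.warning("icc_bootstrap_ci: dropped %d/%d non-convergent "
                       "replicates", dropped, B)
    vals = np.array(values)
    mean = float(vals.mean())
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return IccBootstrap(mean=mean, lower=float(min(lo, mean)),
                        upper=float(max(hi, mean)), values=vals,
                        n_dropped=dropped)


# --------------------------------------------------------------------------
# Odds ratios and classification metrics
# --------------------------------------------------------------------------

def odds_ratios(model: FittedModel) -> pd.DataFrame:
    """exp(beta) per coefficient (reference categories implicitly OR = 1)."""
    return pd.DataFrame({
        "term": model.names,
        "coefficient": model.beta,
        "se": model.se,
        "odds_ratio": np.exp(model.beta),
    })


def combined_or(model: FittedModel, coefficient_names: Sequence[str]) -> float:
    """exp of the sum of the named coefficients.

    Used e.g. for the total ethnic-woman-with-same-ethnic-partner effect,
    combining the ethnicity main effect with the interaction term.
    """
    return float(math.exp(sum(model.coef(n) for n in coefficient_names)))


def fitted_probabilities(model: FittedModel, data: pd.DataFrame
                         ) -> np.ndarray:
    """In-sample predicted probabilities (fixed effects + domain modes)."""
    X, _ = design_matrix(data, model.codebook)
    dom = domain_labels(data).to_numpy()
    v = np.array([model.v_hat.get(d, 0.0) for d in dom])
    return expit(X @ model.beta + v)


def classification_metrics(model: FittedModel, survey: pd.DataFrame,
                           threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics of the in-sample classifier 1{p_hat >= t}.

    Returns accuracy (P11+P00)/n, precision P11/(P11+P01), sensitivity
    P11/(P11+P10) and specificity P00/(P00+P01); a metric whose denominator
    is an empty class is reported as None rather than NaN.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    y = survey[OUTCOME_FOR_INDICATOR[model.indicator]].to_numpy()
    yhat = (fitted_probabilities(model, survey) >= threshold).astype(int)
    p11 = int(np.sum((y == 1) & (yhat == 1)))
    p00 = int(np.sum((y == 0) & (yhat == 0)))
    p01 = int(np.sum((y == 0) & (yhat == 1)))   # false positive
    p10 = int(np.sum((y == 1) & (yhat == 0)))   # false negative
    return metrics_from_counts(p11, p00, p01, p10)


def metrics_from_counts(p11: int, p00: int, p01: int, p10: int) -> dict:
    """Metrics from confusion counts (P11 true pos, P00 true neg,
    P01 false pos, P10 false neg)."""
    total = p11 + p00 + p01 + p10
    div = lambda a, b: a / b if b > 0 else None
    return {
        "accuracy": div(p11 + p00, total),
        "precision": div(p11, p11 + p01),
        "sensitivity": div(p11, p11 + p10),
        "specificity": div(p00, p00 + p01),
        "counts": {"P11": p11, "P00": p00, "P01": p01, "P10": p10},
    }
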