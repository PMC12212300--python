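"""Synthetic populations with known truth for the SAE pipeline.

Emulates the joint structure of the real inputs: a census-like population of
married/in-union women aged 13-49 spread over states x three ethnic groups x
rural/urban, covariates drawn from per-domain categorical distributions,
Bernoulli outcomes from the unit-level logit linking model with one random
intercept per (ethnic group, state) domain, and an unequal-probability
stratified survey draw with inverse-inclusion-probability weights.

The three outcome models are marginal; a joint law is built hierarchically:
any-use is drawn from its model, modern use among users with conditional
probability p_modern/p_any (capped at 1), unmet need among non-users with
p_unmet/(1-p_any) (capped at 1).  This reproduces all three marginals when
the caps do not bind; cap events are counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_data import (AGE_GROUPS, Codebook, EDUCATION, MODELLED_INDICATORS,
                        design_matrix)
from .reference_models import DEFAULT_SIGMA_V, PUBLISHED_ESTIMATES

logger = logging.getLogger("ethnosae")

_BINARY_COVARIATES = ("is_mother", "not_attending_school", "working",
                      "poor_walls", "house_or_apartment", "electricity",
                      "internet", "partner_same_ethnic")


@dataclass
class TruthParams:
    """Ground-truth parameters of the synthetic generative model.

    beta : indicator -> {coefficient name -> value}, aligned to the codebook.
    sigma_v : indicator -> latent random-intercept SD (>= 0).
    covariate_dists : "ethnic|urbanicity" -> distribution spec with keys
        ``age_group`` and ``education`` (level -> probability, summing to 1)
        plus one Bernoulli probability per binary covariate.
    domain_sizes : "state|ethnic|urbanicity" -> population count (>= 0).
    seed : base seed for reproducible generation.
    """
    beta: dict[str, dict[str, float]]
    sigma_v: dict[str, float]
    covariate_dists: dict[str, dict]
    domain_sizes: dict[str, int]
    seed: int = 0
    codebook: Codebook = field(default_factory=Codebook)

    def __post_init__(self):
        for k, s in self.sigma_v.items():
            if s < 0:
                raise ValueError(f"sigma_v[{k!r}] must be >= 0")
        for n in self.domain_sizes.values():
            if n < 0:
                raise ValueError("domain sizes must be >= 0")
        for key, dist in self.covariate_dists.items():
            for var in ("age_group", "education"):
                tot = sum(dist[var].values())
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(
                        f"covariate_dists[{key!r}][{var!r}] sums to {tot}")

    @classmethod
    def from_yaml(cls, path) -> "TruthParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(beta=d["beta"], sigma_v=d["sigma_v"],
                   covariate_dists=d["covariate_dists"],
                   domain_sizes=d["domain_sizes"],
                   seed=int(d.get("seed", 0)))

    def to_yaml(self, path) -> None:
        d = {"beta": self.beta, "sigma_v": self.sigma_v,
             "covariate_dists": self.covariate_dists,
             "domain_sizes": self.domain_sizes, "seed": self.seed}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def default_covariate_dists() -> dict[str, dict]:
    """Per-domain covariate distributions with realistic gradients.

    Education, housing quality, electricity and internet access decrease
    from non-ethnic urban to Indigenous rural domains; same-ethnic
    partnership is about two-thirds for ethnic women.
    """
    age = dict(zip(AGE_GROUPS,
                   (0.02, 0.12, 0.16, 0.17, 0.16, 0.14, 0.12, 0.11)))
    edu = {
        ("nonethnic", "urban"): (0.03, 0.17, 0.55, 0.25),
        ("nonethnic", "rural"): (0.10, 0.35, 0.45, 0.10),
        ("afro", "urban"): (0.05, 0.22, 0.53, 0.20),
        ("afro", "rural"): (0.12, 0.38, 0.42, 0.08),
        ("indigenous", "urban"): (0.10, 0.30, 0.45, 0.15),
        ("indigenous", "rural"): (0.25, 0.40, 0.30, 0.05),
    }
    poor_walls = {
        ("nonethnic", "urban"): 0.03, ("nonethnic", "rural"): 0.12,
        ("afro", "urban"): 0.08, ("afro", "rural"): 0.25,
        ("indigenous", "urban"): 0.15, ("indigenous", "rural"): 0.40,
    }
    internet = {
        ("nonethnic", "urban"): 0.65, ("nonethnic", "rural"): 0.15,
        ("afro", "urban"): 0.50, ("afro", "rural"): 0.08,
        ("indigenous", "urban"): 0.35, ("indigenous", "rural"): 0.05,
    }
    dists: dict[str, dict] = {}
    for eth in ("indigenous", "afro", "nonethnic"):
        for urb in ("rural", "urban"):
            key = f"{eth}|{urb}"
            dists[key] = {
                "age_group": dict(age),
                "education": dict(zip(EDUCATION, edu[(eth, urb)])),
                "is_mother": 0.75 if urb == "rural" else 0.70,
                "not_attending_school": 0.90 if urb == "rural" else 0.80,
                "working": 0.35 if urb == "rural" else 0.55,
                "poor_walls": poor_walls[(eth, urb)],
                "house_or_apartment":
                    0.70 if (eth, urb) == ("indigenous", "rural")
                    else (0.85 if urb == "rural" else 0.92),
                "electricity":
                    0.60 if (eth, urb) == ("indigenous", "rural")
                    else (0.85 if urb == "rural" else 0.99),
                "internet": internet[(eth, urb)],
                "partner_same_ethnic": 0.90 if eth == "nonethnic" else 0.67,
            }
    return dists


def default_domain_sizes(n_states: int = 6, rows_per_state: int = 2000
                         ) -> dict[str, int]:
    """Population counts per state x ethnic group x urbanicity.

    Ethnic composition and rural share vary across states (some states
    Indigenous-heavy and rural, some urban and predominantly non-ethnic),
    cycling over six profiles for larger state counts.
    """
    ind_share = (0.35, 0.10, 0.05, 0.45, 0.15, 0.08)
    afro_share = (0.10, 0.30, 0.08, 0.05, 0.25, 0.12)
    rural_share = (0.60, 0.30, 0.20, 0.70, 0.40, 0.25)
    sizes: dict[str, int] = {}
    for s in range(1, n_states + 1):
        k = (s - 1) % 6
        shares = {"indigenous": ind_share[k], "afro": afro_share[k]}
        shares["nonethnic"] = 1.0 - shares["indigenous"] - shares["afro"]
        for eth, p_eth in shares.items():
            for urb, p_urb in (("rural", rural_share[k]),
                               ("urban", 1 - rural_share[k])):
                sizes[f"{s}|{eth}|{urb}"] = int(round(
                    rows_per_state * p_eth * p_urb))
    return sizes


def default_truth(n_states: int = 6, rows_per_state: int = 2000,
                  seed: int = 0) -> TruthParams:
    """Default study conditions: published coefficient vectors as truth,
    random-intercept SDs matching the published latent-scale ICCs
    (~0.076 / 0.070 / 0.058), six states of 2,000 women each."""
    beta = {ind: {k: v[0] for k, v in PUBLISHED_ESTIMATES[ind].items()}
            for ind in MODELLED_INDICATORS}
    return TruthParams(beta=beta,
                       sigma_v=dict(DEFAULT_SIGMA_V),
                       covariate_dists=default_covariate_dists(),
                       domain_sizes=default_domain_sizes(n_states,
                                                         rows_per_state),
                       seed=seed)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_population(params: TruthParams, rng=None
                        ) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Draw a census-like population and the domain random intercepts.

    Returns ``(population, v_draws)`` where ``v_draws[indicator]`` maps
    domain keys "ethnic|state" to the drawn N(0, sigma_v^2) intercepts.
    All rows are in-union (the eligible population is generated directly).
    """
    if not params.domain_sizes:
        raise ValueError("domain_sizes is empty")
    rng = _as_rng(params.seed if rng is None else rng)

    frames = []
    for key in sorted(params.domain_sizes,
                      key=lambda k: (int(k.split("|")[0]), k)):
        state_s, eth, urb = key.split("|")
        n = params.domain_sizes[key]
        if n == 0:
            continue
        dist = params.covariate_dists[f"{eth}|{urb}"]
        block = {
            "state": np.full(n, int(state_s)),
            "ethnic_group": np.full(n, eth, dtype=object),
            "urbanicity": np.full(n, urb, dtype=object),
            "in_union": np.ones(n, dtype=np.int8),
            "age_group": rng.choice(list(dist["age_group"]), size=n,
                                    p=list(dist["age_group"].values())),
            "education": rng.choice(list(dist["education"]), size=n,
                                    p=list(dist["education"].values())),
        }
        for c in _BINARY_COVARIATES:
            block[c] = (rng.random(n) < dist[c]).astype(np.int8)
        frames.append(pd.DataFrame(block))
    if not frames:
        pop = pd.DataFrame(columns=["state", "ethnic_group", "urbanicity",
                                    "in_union", "age_group", "education",
                                    *_BINARY_COVARIATES])
    else:
        pop = pd.concat(frames, ignore_index=True)
    pop.insert(0, "id", [f"c{i:07d}" for i in range(len(pop))])

    domains = sorted({(k.split("|")[1], int(k.split("|")[0]))
                      for k in params.domain_sizes})
    v_draws: dict[str, dict[str, float]] = {}
    for ind in MODELLED_INDICATORS:
        sd = params.sigma_v[ind]
        v_draws[ind] = {f"{eth}|{st}": float(rng.normal(0.0, sd))
                        for eth, st in domains}
    return pop, v_draws


def assign_outcomes(population: pd.DataFrame, params: TruthParams,
                    v_draws: Mapping[str, Mapping[str, float]], rng
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Draw the three binary outcomes from the logit linking models.

    Hierarchical construction (any use first, then modern among users and
    unmet among non-users) guarantees the outcome-consistency invariants by
    construction while matching the three marginal models whenever the
    conditional probabilities stay within [0, 1].
    """
    rng = _as_rng(rng)
    out = population.copy()
    n = len(out)
    if n == 0:
        for c in ("y_use_any", "y_use_modern", "y_unmet"):
            out[c] = np.array([], dtype=np.int8)
        return out, {"cap_modern": 0, "cap_unmet": 0}

    X, names = design_matrix(out, params.codebook)
    dom = (out["ethnic_group"].astype(str) + "|"
           + out["state"].astype(str)).to_numpy()
    p = {}
    from scipy.special import expit
    for ind in MODELLED_INDICATORS:
        beta = np.array([params.beta[ind][nm] for nm in names])
        v = np.array([v_draws[ind][d] for d in dom])
        p[ind] = expit(X @ beta + v)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_mod_given_any = np.where(p["use_any"] > 0,
                                   p["use_modern"] / p["use_any"], 0.0)
        p_unmet_given_non = np.where(p["use_any"] < 1,
                                     p["unmet"] / (1 - p["use_any"]), 0.0)
    cap_modern = int(np.sum(p_mod_given_any > 1))
    cap_unmet = int(np.sum(p_unmet_given_non > 1))
    if cap_modern or cap_unmet:
        logger.info("assign_outcomes: capped conditional probabilities "
                    "(modern: %d rows, unmet: %d rows)", cap_modern, cap_unmet)
    p_mod_given_any = np.clip(p_mod_given_any, 0.0, 1.0)
    p_unmet_given_non = np.clip(p_unmet_given_non, 0.0, 1.0)

    u1, u2, u3 = rng.random(n), rng.random(n), rng.random(n)
    y_any = (u1 < p["use_any"]).astype(np.int8)
    y_mod = (y_any & (u2 < p_mod_given_any)).astype(np.int8)
    y_unmet = ((1 - y_any) & (u3 < p_unmet_given_non)).astype(np.int8)
    out["y_use_any"] = y_any
    out["y_use_modern"] = y_mod
    out["y_unmet"] = y_unmet
    return out, {"cap_modern": cap_modern, "cap_unmet": cap_unmet}


def draw_survey(population: pd.DataFrame, fractions, seed,
                strata: tuple[str, ...] = ("state", "urbanicity")
                ) -> pd.DataFrame:
    """Stratified simple random sample with design weights.

    ``fractions`` is a single sampling fraction in (0, 1] or a mapping from
    stratum key (values of ``strata`` joined by "|") to a fraction.  Each
    sampled row receives weight N_h / n_h, the inverse inclusion
    probability within its stratum.
    """
    rng = _as_rng(seed)
    key = population[list(strata)].astype(str).agg("|".join, axis=1)
    parts = []
    for h in sorted(key.unique()):
        f = fractions.get(h) if isinstance(fractions, Mapping) else fractions
        if f is None:
            raise ValueError(f"no sampling fraction for stratum {h!r}")
        if not 0 < f <= 1:
            raise ValueError(f"sampling fraction for stratum {h!r} must be "
                             f"in (0, 1], got {f}")
        idx = np.flatnonzero((key == h).to_numpy())
        n_h = max(1, int(round(f * len(idx))))
        take = np.sort(rng.choice(idx, size=n_h, replace=False))
        block = population.iloc[take].copy()
        block["weight"] = len(idx) / n_h
        parts.append(block)
    return pd.concat(parts, ignore_index=True)


@dataclass
class Simulation:
    """One realized synthetic study: population with outcomes, the survey
    sample drawn from it, the drawn random intercepts and the realized
    per-domain truth table."""
    population: pd.DataFrame
    survey: pd.DataFrame
    v_draws: dict[str, dict[str, float]]
    truth: pd.DataFrame
    cap_events: dict[str, int]

    @property
    def census(self) -> pd.DataFrame:
        """Census view of the population: outcomes and weight dropped."""
        return self.population.drop(
            columns=["y_use_any", "y_use_modern", "y_unmet"])


def domain_truth(population: pd.DataFrame) -> pd.DataFrame:
    """Realized true domain proportions of the four indicators.

    Need satisfied is the ratio of realized domain means:
    mean(y_modern) / (mean(y_any) + mean(y_unmet)).
    """
    g = population.groupby(["ethnic_group", "state"], observed=True)
    t = g[["y_use_any", "y_use_modern", "y_unmet"]].mean()
    t.columns = ["use_any", "use_modern", "unmet"]
    denom = t["use_any"] + t["unmet"]
    t["need_satisfied"] = np.where(denom > 0, t["use_modern"] / denom, np.nan)
    t["n"] = g.size()
    return t.reset_index()


def simulate(params: TruthParams, fractions=0.25, seed: int | None = None
             ) -> Simulation:
    """Generate population, outcomes and a survey draw in one call."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pop, v_draws = generate_population(params, rng)
    pop, caps = assign_outcomes(pop, params, v_draws, rng)
    survey = draw_survey(pop, fractions, rng)
    return Simulation(population=pop, survey=survey, v_draws=v_draws,
                      truth=domain_truth(pop), cap_events=caps)
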