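"""Published logistic-GLMM estimates for the three contraceptive-use models.

These are the fixed-effect estimates (with standard errors and printed odds
ratios) of the unit-level mixed-effects logistic models fitted to the 2015
Colombian DHS for married/in-union women aged 13-49, one model per
indicator: any contraceptive use, modern contraceptive use, and unmet need
for family planning.  The package uses them in two roles:

* as the default ground-truth coefficient vectors of the synthetic-data
  generator, so simulated populations have realistic effect sizes; and
* as inputs for odds-ratio arithmetic (single, combined across terms).

The published latent-scale intraclass correlations (mean and 95% bootstrap
CI) determine the default random-intercept standard deviations.
"""

from __future__ import annotations

import math

import numpy as np

from .core_data import Codebook

# (coefficient, standard error, published odds ratio) per covariate,
# in the fixed codebook order.
PUBLISHED_ESTIMATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "use_any": {
        "intercept": (-3.538, 0.373, 0.029),
        "age_13_14": (0.309, 0.515, 1.362),
        "age_15_19": (0.815, 0.108, 2.259),
        "age_20_24": (0.927, 0.081, 2.526),
        "age_25_29": (0.837, 0.073, 2.310),
        "age_30_34": (1.023, 0.075, 2.781),
        "age_35_39": (0.790, 0.074, 2.204),
        "age_40_44": (0.731, 0.077, 2.077),
        "is_mother": (0.688, 0.022, 1.990),
        "edu_primary": (0.981, 0.161, 2.668),
        "edu_secondary": (1.396, 0.162, 4.039),
        "edu_higher": (1.347, 0.168, 3.847),
        "not_attending_school": (-0.256, 0.106, 0.774),
        "working": (0.016, 0.044, 1.016),
        "poor_walls": (-0.197, 0.084, 0.821),
        "house_or_apartment": (1.148, 0.315, 3.153),
        "electricity": (0.289, 0.145, 1.335),
        "internet": (0.208, 0.050, 1.232),
        "partner_same_ethnic": (0.213, 0.061, 1.237),
        "ethnic": (-0.008, 0.157, 0.992),
        "ethnic_x_partner_same": (-0.304, 0.130, 0.738),
    },
    "use_modern": {
        "intercept": (-3.711, 0.357, 0.024),
        "age_13_14": (0.359, 0.511, 1.432),
        "age_15_19": (0.737, 0.102, 2.089),
        "age_20_24": (0.932, 0.075, 2.540),
        "age_25_29": (0.834, 0.067, 2.301),
        "age_30_34": (0.888, 0.067, 2.430),
        "age_35_39": (0.685, 0.066, 1.984),
        "age_40_44": (0.605, 0.069, 1.831),
        "is_mother": (0.577, 0.019, 1.780),
        "edu_primary": (0.993, 0.147, 2.699),
        "edu_secondary": (1.335, 0.149, 3.801),
        "edu_higher": (1.184, 0.154, 3.268),
        "not_attending_school": (-0.180, 0.098, 0.835),
        "working": (-0.004, 0.040, 0.996),
        "poor_walls": (-0.201, 0.078, 0.818),
        "house_or_apartment": (1.379, 0.304, 3.970),
        "electricity": (0.280, 0.136, 1.323),
        "internet": (0.191, 0.045, 1.210),
        "partner_same_ethnic": (0.172, 0.056, 1.188),
        "ethnic": (-0.055, 0.143, 0.947),
        "ethnic_x_partner_same": (-0.218, 0.120, 0.804),
    },
    "unmet": {
        "intercept": (-0.384, 0.409, 0.681),
        "age_13_14": (1.955, 0.499, 7.063),
        "age_15_19": (0.918, 0.150, 2.504),
        "age_20_24": (0.508, 0.123, 1.661),
        "age_25_29": (0.005, 0.120, 1.005),
        "age_30_34": (-0.335, 0.125, 0.715),
        "age_35_39": (-0.255, 0.125, 0.775),
        "age_40_44": (-0.222, 0.126, 0.801),
        "is_mother": (-0.156, 0.028, 0.856),
        "edu_primary": (-0.425, 0.200, 0.654),
        "edu_secondary": (-0.798, 0.206, 0.450),
        "edu_higher": (-0.858, 0.218, 0.424),
        "not_attending_school": (0.465, 0.157, 1.592),
        "working": (-0.098, 0.070, 0.906),
        "poor_walls": (0.025, 0.115, 1.025),
        "house_or_apartment": (-0.532, 0.329, 0.587),
        "electricity": (-0.256, 0.175, 0.774),
        "internet": (-0.066, 0.079, 0.936),
        "partner_same_ethnic": (-0.502, 0.085, 0.605),
        "ethnic": (-0.149, 0.170, 0.861),
        "ethnic_x_partner_same": (0.403, 0.178, 1.496),
    },
}

#: published latent-scale ICC (mean, lower95, upper95) per indicator
PUBLISHED_ICC: dict[str, tuple[float, float, float]] = {
    "use_any": (0.076, 0.0476, 0.115),
    "use_modern": (0.070, 0.0431, 0.110),
    "unmet": (0.058, 0.0262, 0.101),
}


def sigma_v_from_icc(icc: float) -> float:
    """Latent-scale random-intercept SD implied by an ICC value.

    Inverts ICC = sigma^2 / (sigma^2 + pi^2/3).
    """
    if not 0 <= icc < 1:
        raise ValueError("icc must be in [0, 1)")
    return math.sqrt(icc / (1.0 - icc) * math.pi ** 2 / 3.0)


#: default generator random-intercept SDs matching the published ICC means
DEFAULT_SIGMA_V: dict[str, float] = {
    k: sigma_v_from_icc(v[0]) for k, v in PUBLISHED_ICC.items()
}


def published_coefficients(indicator: str,
                           codebook: Codebook | None = None
                           ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return ``(beta, se, names)`` aligned to the codebook column order."""
    codebook = codebook or Codebook()
    table = PUBLISHED_ESTIMATES[indicator]
    names = codebook.names_with_intercept
    beta = np.array([table[n][0] for n in names])
    se = np.array([table[n][1] for n in names])
    return beta, se, names


def published_model(indicator: str):
    """The published fixed effects wrapped as a FittedModel.

    ``sigma_v`` is set from the published ICC; no random-intercept
    predictions are available (empty ``v_hat``), so predictions from this
    model are fixed-effects only.
    """
    from .model_fit import FittedModel  # deferred: avoid circular import

    beta, se, names = published_coefficients(indicator)
    return FittedModel(
        indicator=indicator,
        names=list(names),
        beta=beta,
        se=se,
        sigma_v=DEFAULT_SIGMA_V[indicator],
        v_hat={},
        loglik=float("nan"),
        converged=True,
        n_obs=0,
        n_domains=0,
        codebook=Codebook(),
    )
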