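"""Microdata model, eligibility filtering, harmonization and design matrices.

Survey and census microdata are handled as pandas DataFrames validated
against a shared codebook: one row per married/in-union woman aged 13-49,
with the household and individual covariates used by the contraceptive-use
models, plus (survey only) a positive sampling weight and the three binary
outcomes.  Categorical variables are strings in CSV files and pandas
categoricals (integer codes) in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ethnosae")

# --------------------------------------------------------------------------
# Shared codebook of categories
# --------------------------------------------------------------------------

ETHNIC_GROUPS = ("indigenous", "afro", "nonethnic")
URBANICITY = ("rural", "urban")
AGE_GROUPS = ("13-14", "15-19", "20-24", "25-29", "30-34",
              "35-39", "40-44", "45-49")
EDUCATION = ("none", "primary", "secondary", "higher")

#: binary 0/1 fields shared by both sources
BINARY_FIELDS = ("in_union", "is_mother", "not_attending_school", "working",
                 "poor_walls", "house_or_apartment", "electricity",
                 "internet", "partner_same_ethnic")

OUTCOME_COLUMNS = ("y_use_any", "y_use_modern", "y_unmet")

INDICATORS = ("use_any", "use_modern", "unmet", "need_satisfied")
#: indicators with their own fitted model (need_satisfied is derived)
MODELLED_INDICATORS = ("use_any", "use_modern", "unmet")

OUTCOME_FOR_INDICATOR = {
    "use_any": "y_use_any",
    "use_modern": "y_use_modern",
    "unmet": "y_unmet",
}

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "ethnic_group": ETHNIC_GROUPS,
    "urbanicity": URBANICITY,
    "age_group": AGE_GROUPS,
    "education": EDUCATION,
}

SHARED_COLUMNS = ("id", "state", "ethnic_group", "urbanicity", "age_group",
                  "in_union", "is_mother", "education",
                  "not_attending_school", "working", "poor_walls",
                  "house_or_apartment", "electricity", "internet",
                  "partner_same_ethnic")
SURVEY_COLUMNS = SHARED_COLUMNS + ("weight",) + OUTCOME_COLUMNS
CENSUS_COLUMNS = SHARED_COLUMNS

DEFAULT_N_STATES = 33


class SchemaError(ValueError):
    """A required column is missing or a forbidden column is present."""


class MicrodataValidationError(ValueError):
    """A row violates the microdata invariants."""


class HarmonizationError(ValueError):
    """A source category has no harmonized mapping."""


# --------------------------------------------------------------------------
# Validation / IO
# --------------------------------------------------------------------------

def validate_microdata(df: pd.DataFrame, source: str, *,
                       n_states: int = DEFAULT_N_STATES,
                       exclusive_unmet: bool = True,
                       drop_missing: bool = False) -> pd.DataFrame:
    """Validate raw microdata rows and return a typed copy.

    Parameters
    ----------
    df : raw table with the declared schema for ``source``.
    source : ``"survey"`` or ``"census"``.
    n_states : number of state codes (1..n_states accepted).
    exclusive_unmet : enforce that unmet need and current use are mutually
        exclusive (standard DHS semantics).  Relax for data sources that
        code the states differently.
    drop_missing : if True, rows with missing values are dropped (listwise)
        with a logged count; by default missing values are rejected.

    Returns a DataFrame with categorical dtypes and integer binaries.
    """
    if source not in ("survey", "census"):
        raise ValueError(f"unknown source {source!r}")
    required = SURVEY_COLUMNS if source == "survey" else CENSUS_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{source} data missing required columns: {missing}")
    if source == "census":
        forbidden = [c for c in ("weight",) + OUTCOME_COLUMNS
                     if c in df.columns]
        if forbidden:
            raise SchemaError(
                f"census data must not contain survey-only columns: {forbidden}")

    out = df.loc[:, list(required)].copy()
    if out.isna().any().any():
        if drop_missing:
            n0 = len(out)
            out = out.dropna()
            logger.info("validate_microdata: dropped %d rows with missing "
                        "values (listwise deletion)", n0 - len(out))
        else:
            bad = out.isna().any(axis=1)
            row = int(np.flatnonzero(bad.to_numpy())[0])
            col = out.columns[out.iloc[row].isna().to_numpy()][0]
            raise MicrodataValidationError(
                f"missing value at row {df.index[row]}, field {col!r}")

    for col, levels in CATEGORICAL_LEVELS.items():
        vals = out[col].astype(str)
        bad = ~vals.isin(levels)
        if bad.any():
            row = out.index[bad][0]
            raise MicrodataValidationError(
                f"unknown category {vals[row]!r} at row {row}, field {col!r}")
        out[col] = pd.Categorical(vals, categories=levels)

    state = pd.to_numeric(out["state"], errors="coerce")
    if state.isna().any() or not ((state >= 1) & (state <= n_states)).all():
        row = out.index[(state.isna() | (state < 1) | (state > n_states))][0]
        raise MicrodataValidationError(
            f"state code out of 1..{n_states} at row {row}")
    out["state"] = state.astype(int)

    binaries = list(BINARY_FIELDS)
    if source == "survey":
        binaries += list(OUTCOME_COLUMNS)
    for col in binaries:
        v = pd.to_numeric(out[col], errors="coerce")
        if v.isna().any() or not v.isin([0, 1]).all():
            row = out.index[~v.isin([0, 1])][0]
            raise MicrodataValidationError(
                f"non-binary value at row {row}, field {col!r}")
        out[col] = v.astype(np.int8)

    if source == "survey":
        w = pd.to_numeric(out["weight"], errors="coerce")
        if w.isna().any() or not (w > 0).all():
            row = out.index[~(w > 0)][0]
            raise MicrodataValidationError(
                f"non-positive sampling weight at row {row}")
        out["weight"] = w.astype(float)
        if (out["y_use_modern"] > out["y_use_any"]).any():
            row = out.index[(out["y_use_modern"] > out["y_use_any"])][0]
            raise MicrodataValidationError(
                f"modern use without any use at row {row}")
        if exclusive_unmet and ((out["y_unmet"] == 1)
                                & (out["y_use_any"] == 1)).any():
            row = out.index[(out["y_unmet"] == 1) & (out["y_use_any"] == 1)][0]
            raise MicrodataValidationError(
                f"unmet need recorded for a current user at row {row}")
    return out.reset_index(drop=True)


def read_microdata(path, source: str, **kwargs) -> pd.DataFrame:
    """Read a survey or census microdata CSV and validate it."""
    df = pd.read_csv(path)
    return validate_microdata(df, source, **kwargs)


def write_microdata(df: pd.DataFrame, path) -> None:
    """Write microdata to CSV with categories as strings.

    Floats are written with shortest round-trip repr, so a read→write→read
    cycle is lossless for weights.
    """
    df.to_csv(path, index=False)


def filter_eligible(df: pd.DataFrame,
                    in_union: Sequence[int] | str = "in_union"
                    ) -> pd.DataFrame:
    """Keep married/in-union women aged 13-49.

    ``in_union`` is either the name of a 0/1 column in ``df`` or an explicit
    per-row indicator.  Rows whose ``age_group`` falls outside the eight
    reproductive-age bands (e.g. "50-54" in an unfiltered extract) are
    removed rather than rejected.
    """
    if isinstance(in_union, str):
        flag = pd.to_numeric(df[in_union], errors="coerce").fillna(0)
    else:
        flag = pd.Series(np.asarray(in_union), index=df.index)
    mask = (flag.to_numpy() == 1) & df["age_group"].astype(str).isin(AGE_GROUPS).to_numpy()
    return df.loc[mask].reset_index(drop=True)


# --------------------------------------------------------------------------
# Harmonization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizationMap:
    """Mapping from one source's raw categories to the shared codebook.

    ``mapping`` must be total over the declared raw categories; values
    already in the harmonized codomain pass through unchanged, which makes
    harmonization idempotent.  ``default`` controls unmapped categories:
    ``"error"`` raises, ``"missing"`` yields NA (handled downstream by the
    missing-value policy).
    """
    variable: str
    source: str  # "survey" | "census"
    mapping: Mapping[object, object]
    default: str = "error"

    def __post_init__(self):
        if self.source not in ("survey", "census"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.default not in ("error", "missing"):
            raise ValueError(f"unknown default policy {self.default!r}")

    def apply(self, values: pd.Series) -> pd.Series:
        codomain = set(self.mapping.values())
        out = []
        for v in values:
            if v in codomain:          # already harmonized
                out.append(v)
            elif v in self.mapping:
                out.append(self.mapping[v])
            elif self.default == "missing":
                out.append(np.nan)
            else:
                raise HarmonizationError(
                    f"variable {self.variable!r} ({self.source}): "
                    f"unmapped category {v!r}")
        return pd.Series(out, index=values.index)


def harmonize(df: pd.DataFrame, maps: Iterable[HarmonizationMap],
              source: str) -> pd.DataFrame:
    """Apply every harmonization map for ``source`` to ``df``.

    Mapped variables must be present; the output uses the shared codebook
    categories so that survey and census files become directly comparable.
    """
    out = df.copy()
    for m in maps:
        if m.source != source:
            continue
        if m.variable not in out.columns:
            raise SchemaError(
                f"harmonization variable {m.variable!r} not in data")
        out[m.variable] = m.apply(out[m.variable])
    return out


def load_harmonization_maps(path) -> list[HarmonizationMap]:
    """Load harmonization maps from a multi-document YAML file.

    Each document has keys ``variable``, ``source``, ``mapping`` and
    optionally ``default``.
    """
    with open(path) as fh:
        docs = [d for d in yaml.safe_load_all(fh) if d]
    return [HarmonizationMap(variable=d["variable"], source=d["source"],
                             mapping=d["mapping"],
                             default=d.get("default", "error"))
            for d in docs]


def default_wall_maps() -> list[HarmonizationMap]:
    """Built-in wall-material harmonization (poor_walls 0/1).

    Survey categories naming inadequate materials (no walls, natural walls,
    cane/palm/trunks, dirt, cardboard, reused wood, uncovered adobe, bamboo
    with mud, plywood) and their census counterparts (guadua, rough wood,
    board/plank, cane/mat/other vegetation, no walls, waste materials) map
    to 1; finished materials map to 0 in both sources.
    """
    ref = resources.files("ethnosae").joinpath("data/wall_materials.yaml")
    with resources.as_file(ref) as p:
        return load_harmonization_maps(p)


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

#: expansion of each codebook term into dummy column names
_TERM_COLUMNS = {
    "age_group": tuple(f"age_{a.replace('-', '_')}" for a in AGE_GROUPS[:-1]),
    "education": ("edu_primary", "edu_secondary", "edu_higher"),
    "ethnicity": ("ethnic",),
    "ethnicity_x_partner": ("ethnic_x_partner_same",),
}

DEFAULT_TERMS = ("age_group", "is_mother", "education",
                 "not_attending_school", "working", "poor_walls",
                 "house_or_apartment", "electricity", "internet",
                 "partner_same_ethnic", "ethnicity", "ethnicity_x_partner")


@dataclass(frozen=True)
class Codebook:
    """Ordered covariate list with fixed reference categories.

    Reference categories (excluded from the dummy expansion): aged 45-49,
    not a mother, no education, attending school, not working, good wall
    material, dwelling other than house or apartment, no electricity, no
    internet, partner from a different ethnic group, non-ethnic woman.
    """
    terms: tuple[str, ...] = DEFAULT_TERMS

    def __post_init__(self):
        for t in self.terms:
            if t not in _TERM_COLUMNS and t not in BINARY_FIELDS:
                raise ValueError(f"unknown codebook term {t!r}")

    @property
    def column_names(self) -> list[str]:
        """Covariate column names in fixed order (intercept excluded)."""
        names: list[str] = []
        for t in self.terms:
            names.extend(_TERM_COLUMNS.get(t, (t,)))
        return names

    @property
    def names_with_intercept(self) -> list[str]:
        return ["intercept"] + self.column_names


def design_matrix(df: pd.DataFrame, codebook: Codebook | None = None
                  ) -> tuple[np.ndarray, list[str]]:
    """Expand validated microdata into the model design matrix.

    Returns ``(X, names)`` where X has an intercept column followed by the
    codebook dummies in fixed order; the reference profile maps to a row
    that is zero apart from the intercept.
    """
    codebook = codebook or Codebook()
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    ethnic = df["ethnic_group"].astype(str).isin(("afro", "indigenous"))
    ethnic = ethnic.to_numpy().astype(float)
    for t in codebook.terms:
        if t == "age_group":
            ag = df["age_group"].astype(str).to_numpy()
            for a in AGE_GROUPS[:-1]:
                cols.append((ag == a).astype(float))
        elif t == "education":
            ed = df["education"].astype(str).to_numpy()
            for lev in ("primary", "secondary", "higher"):
                cols.append((ed == lev).astype(float))
        elif t == "ethnicity":
            cols.append(ethnic)
        elif t == "ethnicity_x_partner":
            partner = df["partner_same_ethnic"].to_numpy().astype(float)
            cols.append(ethnic * partner)
        else:
            cols.append(df[t].to_numpy().astype(float))
    X = np.column_stack(cols)
    return X, codebook.names_with_intercept


def domain_labels(df: pd.DataFrame) -> pd.Series:
    """Domain key "<ethnic_group>|<state>" per row."""
    return df["ethnic_group"].astype(str) + "|" + df["state"].astype(str)
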