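"""Synthetic survey data with the statistical structure the analysis assumes.

The analysis targets a nationwide telephone survey of German-speaking
adults (>=18 years) without known diabetes whose record-level data are
access-restricted.  This module therefore generates survey-like datasets
that emulate the published statistical structure at two levels:

* **outcome-level** -- GDRS totals drawn directly from the two-level
  random-intercept model (individuals nested in 12 intersectional
  strata), using the published stratum sizes, grand mean, fixed effects
  and variance components as defaults;
* **component-level** -- raw risk-factor fields (height, weight,
  smoking, ...) that the GDRS scorer must score end-to-end.  Per-stratum
  component distributions are not published; the ones used here are
  documented fixture choices, recorded in the output metadata and
  configurable.

Missingness is injected completely at random in the published counts
(7 records missing a social dimension, 67 missing a score component, out
of 2,327 pre-exclusion records), so the downstream exclusion filter
reproduces the published accounting exactly (2,327 - 7 - 67 = 2,253).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gdrs as gdrs_mod

__all__ = [
    "PopulationConfig", "STUDY_STRATUM_SIZES", "STUDY_STRATUM_MEANS",
    "STUDY_FIXED_EFFECTS", "generate_outcome_level", "generate_component_level",
    "inject_missingness", "pad_stratum_sizes", "write_dataset",
]

# ---------------------------------------------------------------------------
# Study conditions the generator emulates (post-exclusion analysis sample).
# Keys are (sex_gender, education, migration).

#: Per-stratum analysis-sample sizes (total 2,253).
STUDY_STRATUM_SIZES: dict[tuple[str, str, str], int] = {
    ("male", "low", "yes"): 23,
    ("female", "low", "yes"): 33,
    ("male", "middle", "yes"): 59,
    ("female", "middle", "yes"): 80,
    ("male", "high", "yes"): 75,
    ("female", "high", "yes"): 71,
    ("male", "low", "no"): 110,
    ("female", "low", "no"): 157,
    ("male", "middle", "no"): 323,
    ("female", "middle", "no"): 494,
    ("male", "high", "no"): 401,
    ("female", "high", "no"): 427,
}

#: Null-model predicted stratum means (GDRS points); used for the
#: "fixed" stratum-effect mode of the generator.
STUDY_STRATUM_MEANS: dict[tuple[str, str, str], float] = {
    ("male", "low", "yes"): 39.08,
    ("female", "low", "yes"): 40.31,
    ("male", "middle", "yes"): 32.77,
    ("female", "middle", "yes"): 35.80,
    ("male", "high", "yes"): 37.98,
    ("female", "high", "yes"): 29.97,
    ("male", "low", "no"): 52.73,
    ("female", "low", "no"): 47.69,
    ("male", "middle", "no"): 40.17,
    ("female", "middle", "no"): 36.96,
    ("male", "high", "no"): 41.49,
    ("female", "high", "no"): 32.78,
}

#: Main-effects model fixed effects (GDRS points; references female,
#: high education, no migration history).
STUDY_FIXED_EFFECTS: dict[str, float] = {
    "intercept": 36.00,
    "male": 4.18,
    "migration": -5.83,
    "education_middle": 1.03,
    "education_low": 10.89,
}

STUDY_GRAND_MEAN = 38.98          # null-model intercept, GDRS points
STUDY_BETWEEN_VAR = 43.79         # between-strata variance, GDRS points^2
STUDY_WITHIN_VAR = 269.00         # within-strata variance, GDRS points^2
STUDY_N_MISSING_SOCIAL = 7        # records missing education or migration
STUDY_N_MISSING_COMPONENTS = 67   # additional records missing a score component
STUDY_N_PREEXCLUSION = 2327       # respondents without known diabetes

_VALID_COEF_NAMES = frozenset(STUDY_FIXED_EFFECTS)

#: Column order of the shared CSV schema (see docs/methods.md).
SCHEMA_COLUMNS = [
    "id", "sex_gender", "education", "migration", "age",
    "height_cm", "weight_kg", "hypertension", "smoking",
    "physical_activity_5h", "coffee_cups_per_day",
    "wholegrain_portions_per_day", "red_meat", "family_history",
    "survey_weight", "gdrs_direct",
]


@dataclass
class PopulationConfig:
    """Configuration of the synthetic survey population.

    Defaults are the study conditions above.  ``mode`` selects
    outcome-level vs component-level generation; ``stratum_effect_mode``
    selects whether stratum effects are drawn fresh from
    N(0, between_var) ("random", for recovery studies) or pinned to the
    published stratum means ("fixed", for regression tests).
    ``effect_structure`` selects the linear predictor: "null"
    (grand mean + stratum effect) or "main_effects" (published fixed
    effects + stratum effect, where between_var is then the residual
    interaction variance).
    """

    stratum_sizes: dict = field(default_factory=lambda: dict(STUDY_STRATUM_SIZES))
    grand_mean: float = STUDY_GRAND_MEAN
    fixed_effects: dict = field(default_factory=lambda: dict(STUDY_FIXED_EFFECTS))
    between_var: float = STUDY_BETWEEN_VAR
    within_var: float = STUDY_WITHIN_VAR
    n_missing_social: int = STUDY_N_MISSING_SOCIAL
    n_missing_components: int = STUDY_N_MISSING_COMPONENTS
    seed: int = 0
    mode: str = "outcome"                 # "outcome" | "component"
    effect_structure: str = "null"        # "null" | "main_effects"
    stratum_effect_mode: str = "random"   # "random" | "fixed"
    stratum_effects: dict | None = None   # explicit u_j for "fixed" mode
    weight_sigma: float = 0.35            # lognormal sd of raw survey weights

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.stratum_sizes:
            raise ValueError("stratum_sizes is empty")
        if any(n <= 0 for n in self.stratum_sizes.values()):
            raise ValueError("all stratum sizes must be > 0")
        if self.between_var < 0 or self.within_var < 0:
            raise ValueError("variances must be >= 0")
        total = sum(self.stratum_sizes.values())
        if self.n_missing_social + self.n_missing_components > total:
            raise ValueError(
                f"requested missingness ({self.n_missing_social}+"
                f"{self.n_missing_components}) exceeds {total} records"
            )
        unknown = set(self.fixed_effects) - _VALID_COEF_NAMES
        if unknown:
            raise ValueError(
                f"unknown fixed-effect coefficient name(s) {sorted(unknown)}; "
                f"known: {sorted(_VALID_COEF_NAMES)}"
            )
        if self.mode not in ("outcome", "component"):
            raise ValueError(f"mode must be 'outcome' or 'component', got {self.mode!r}")
        if self.effect_structure not in ("null", "main_effects"):
            raise ValueError(f"bad effect_structure {self.effect_structure!r}")
        if self.stratum_effect_mode not in ("random", "fixed"):
            raise ValueError(f"bad stratum_effect_mode {self.stratum_effect_mode!r}")

    @property
    def n_total(self) -> int:
        return sum(self.stratum_sizes.values())

    def metadata(self) -> dict:
        meta = dataclasses.asdict(self)
        meta["stratum_sizes"] = {"|".join(k): v for k, v in self.stratum_sizes.items()}
        if isinstance(meta.get("stratum_effects"), dict):
            meta["stratum_effects"] = {"|".join(k): v for k, v in meta["stratum_effects"].items()}
        return meta


def pad_stratum_sizes(sizes: dict, total: int) -> dict:
    """Scale stratum sizes up to ``total`` by largest-remainder allocation.

    Used to emulate the pre-exclusion sample (2,327 records) from the
    analysis-sample allocation before missingness is injected.
    """
    base = sum(sizes.values())
    if total < base:
        raise ValueError(f"total {total} smaller than current allocation {base}")
    keys = list(sizes)
    exact = np.array([sizes[k] * total / base for k in keys])
    floor = np.floor(exact).astype(int)
    remainder = total - floor.sum()
    order = np.argsort(-(exact - floor))
    out = {k: int(v) for k, v in zip(keys, floor)}
    for i in order[:remainder]:
        out[keys[i]] += 1
    return out


def _stratum_frame(config: PopulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for (sex, edu, mig), n in config.stratum_sizes.items():
        for _ in range(n):
            i += 1
            rows.append({"id": i, "sex_gender": sex, "education": edu, "migration": mig})
    return pd.DataFrame(rows)


def _linear_predictor(config: PopulationConfig, df: pd.DataFrame) -> np.ndarray:
    if config.effect_structure == "null":
        return np.full(len(df), config.grand_mean)
    fe = config.fixed_effects
    lp = np.full(len(df), fe.get("intercept", config.grand_mean))
    lp += fe.get("male", 0.0) * (df["sex_gender"] == "male").to_numpy()
    lp += fe.get("migration", 0.0) * (df["migration"] == "yes").to_numpy()
    lp += fe.get("education_middle", 0.0) * (df["education"] == "middle").to_numpy()
    lp += fe.get("education_low", 0.0) * (df["education"] == "low").to_numpy()
    return lp


def _stratum_effects(config: PopulationConfig, rng: np.random.Generator) -> dict:
    keys = list(config.stratum_sizes)
    if config.stratum_effect_mode == "fixed":
        if config.stratum_effects is not None:
            return {k: float(config.stratum_effects[k]) for k in keys}
        # pin to the published null-model stratum means
        return {k: STUDY_STRATUM_MEANS[k] - config.grand_mean for k in keys}
    draws = rng.normal(0.0, np.sqrt(config.between_var), size=len(keys))
    return dict(zip(keys, draws))


def _ages_and_weights(df: pd.DataFrame, rng: np.random.Generator, sigma: float) -> None:
    # respondents with a migration history are on average younger, as in
    # the German resident population; supports age-confounding studies
    mean_age = np.where(df["migration"] == "yes", 45.0, 53.0)
    df["age"] = np.clip(rng.normal(mean_age, 17.0), 18.0, 95.0).round(0)
    df["survey_weight"] = np.exp(rng.normal(0.0, sigma, len(df)))


def generate_outcome_level(config: PopulationConfig) -> pd.DataFrame:
    """Draw GDRS totals directly from the two-level model.

    For each stratum j an effect u_j is obtained (drawn from
    N(0, between_var) or pinned, per config); each individual i in j gets
    ``gdrs_direct`` = linear predictor + u_j + e_ij with
    e_ij ~ N(0, within_var).  Social-dimension fields are set from the
    stratum; age and survey weights are generated for downstream stages.
    Reproducible under a fixed seed.
    """
    if config.mode != "outcome":
        raise ValueError("config.mode must be 'outcome' for generate_outcome_level")
    rng = np.random.default_rng(config.seed)
    df = _stratum_frame(config)
    effects = _stratum_effects(config, rng)
    u = df.apply(lambda r: effects[(r["sex_gender"], r["education"], r["migration"])], axis=1)
    lp = _linear_predictor(config, df)
    e = rng.normal(0.0, np.sqrt(config.within_var), len(df))
    _ages_and_weights(df, rng, config.weight_sigma)
    df["gdrs_direct"] = lp + u.to_numpy() + e
    for col in SCHEMA_COLUMNS:
        if col not in df:
            df[col] = np.nan
    df = df[SCHEMA_COLUMNS]
    df.attrs["metadata"] = {"config": config.metadata(), "generator": "outcome_level"}
    return df


# --------------------------------------------------------------------------
# component-level generation: fixture distributions, documented in metadata

_SMOKING_LABELS = ["never_or_former_lt20", "current_lt20", "former_ge20", "current_ge20"]
_MEAT_LABELS = ["lt1_per_week", "1_6_per_week", "daily", "gt1_per_day"]
_FAMILY_LABELS = ["none", "one_parent", "sibling", "both_parents", "parent_and_sibling"]

#: Fixture component distributions.  Education shifts adiposity, smoking
#: and diet adversely for lower levels; sex shifts anthropometry.  These
#: are documented choices, not published quantities.
COMPONENT_DISTRIBUTIONS = {
    "height_mean": {"male": 178.0, "female": 165.0},
    "height_sd": 7.0,
    "bmi_mean_by_education": {"high": 25.0, "middle": 26.2, "low": 27.5},
    "bmi_sd": 4.0,
    "hypertension_base_logit_age50": -1.1,
    "hypertension_age_slope": 0.055,
    "smoking_probs_by_education": {
        "high": [0.80, 0.10, 0.06, 0.04],
        "middle": [0.70, 0.14, 0.09, 0.07],
        "low": [0.60, 0.17, 0.12, 0.11],
    },
    "activity_prob_by_education": {"high": 0.55, "middle": 0.48, "low": 0.40},
    "coffee_poisson_mean": 2.4,
    "wholegrain_gamma_shape": 1.6,
    "wholegrain_gamma_scale": 0.9,
    "red_meat_probs_by_education": {
        "high": [0.35, 0.45, 0.15, 0.05],
        "middle": [0.25, 0.48, 0.19, 0.08],
        "low": [0.18, 0.47, 0.24, 0.11],
    },
    "family_history_probs": [0.70, 0.13, 0.07, 0.06, 0.04],
}


def generate_component_level(
    config: PopulationConfig,
    point_table: gdrs_mod.GdrsPointTable | None = None,
) -> pd.DataFrame:
    """Generate raw GDRS component fields that the scorer can score.

    The generator shares its category vocabulary with the point table, so
    every complete record is scoreable, and clips continuous draws inside
    the table's declared domains.  ``gdrs_direct`` is left empty.
    """
    if config.mode != "component":
        raise ValueError("config.mode must be 'component' for generate_component_level")
    if point_table is None:
        point_table = gdrs_mod.load_default_point_table()
    dist = COMPONENT_DISTRIBUTIONS
    rng = np.random.default_rng(config.seed)
    df = _stratum_frame(config)
    n = len(df)
    _ages_and_weights(df, rng, config.weight_sigma)

    sex = df["sex_gender"].to_numpy()
    edu = df["education"].to_numpy()
    hmean = np.where(sex == "male", dist["height_mean"]["male"], dist["height_mean"]["female"])
    df["height_cm"] = np.clip(rng.normal(hmean, dist["height_sd"]), 150.0, 200.0).round(1)
    bmi_mean = np.vectorize(dist["bmi_mean_by_education"].get)(edu)
    bmi = np.clip(rng.normal(bmi_mean, dist["bmi_sd"]), 16.5, 44.0)
    df["weight_kg"] = (bmi * (df["height_cm"] / 100.0) ** 2).round(1)
    logit = dist["hypertension_base_logit_age50"] + dist["hypertension_age_slope"] * (
        df["age"].to_numpy() - 50.0
    )
    df["hypertension"] = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    df["smoking"] = [
        rng.choice(_SMOKING_LABELS, p=dist["smoking_probs_by_education"][e]) for e in edu
    ]
    act_p = np.vectorize(dist["activity_prob_by_education"].get)(edu)
    df["physical_activity_5h"] = rng.random(n) < act_p
    df["coffee_cups_per_day"] = np.clip(rng.poisson(dist["coffee_poisson_mean"], n), 0, 12)
    df["wholegrain_portions_per_day"] = np.clip(
        rng.gamma(dist["wholegrain_gamma_shape"], dist["wholegrain_gamma_scale"], n), 0.0, 6.0
    ).round(1)
    df["red_meat"] = [
        rng.choice(_MEAT_LABELS, p=dist["red_meat_probs_by_education"][e]) for e in edu
    ]
    df["family_history"] = rng.choice(_FAMILY_LABELS, size=n, p=dist["family_history_probs"])
    df["gdrs_direct"] = np.nan
    df = df[SCHEMA_COLUMNS]
    df.attrs["metadata"] = {
        "config": config.metadata(),
        "generator": "component_level",
        "component_distributions": dist,
        "point_table": point_table.name,
    }
    return df


_SOCIAL_FIELDS = ("education", "migration")
_COMPONENT_FIELDS = (
    "height_cm", "weight_kg", "hypertension", "smoking", "physical_activity_5h",
    "coffee_cups_per_day", "wholegrain_portions_per_day", "red_meat", "family_history",
)


def inject_missingness(
    records: pd.DataFrame,
    n_missing_social: int,
    n_missing_components: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Blank fields completely at random in exactly the requested counts.

    ``n_missing_social`` records lose education or migration (alternately
    chosen at random); a disjoint set of ``n_missing_components`` records
    loses at least one GDRS component (for outcome-level data, the direct
    score itself).  Raises if the two counts together exceed the number
    of records.
    """
    n = len(records)
    if n_missing_social + n_missing_components > n:
        raise ValueError(
            f"requested missingness ({n_missing_social}+{n_missing_components}) "
            f"exceeds the {n} available records"
        )
    rng = np.random.default_rng(seed)
    out = records.copy()
    # bool columns cannot hold NaN; widen to object before blanking
    for fld in (*_SOCIAL_FIELDS, *_COMPONENT_FIELDS):
        if fld in out and out[fld].dtype == bool:
            out[fld] = out[fld].astype(object)
    chosen = rng.choice(n, size=n_missing_social + n_missing_components, replace=False)
    social_pos = chosen[:n_missing_social]
    comp_pos = chosen[n_missing_social:]
    outcome_level = "gdrs_direct" in out and out["gdrs_direct"].notna().any()
    for pos in social_pos:
        fld = _SOCIAL_FIELDS[rng.integers(len(_SOCIAL_FIELDS))]
        out.iloc[pos, out.columns.get_loc(fld)] = np.nan
    for pos in comp_pos:
        if outcome_level:
            out.iloc[pos, out.columns.get_loc("gdrs_direct")] = np.nan
        else:
            k = int(rng.integers(1, 3))  # blank 1-2 components
            for fld in rng.choice(_COMPONENT_FIELDS, size=k, replace=False):
                out.iloc[pos, out.columns.get_loc(fld)] = np.nan
    out.attrs["metadata"] = dict(records.attrs.get("metadata", {}))
    out.attrs["metadata"]["missingness"] = {
        "n_missing_social": int(n_missing_social),
        "n_missing_components": int(n_missing_components),
        "seed": int(seed),
        "mechanism": "MCAR",
    }
    return out


def write_dataset(df: pd.DataFrame, path: str | Path) -> Path:
    """Write the dataset as CSV with a JSON metadata sidecar (config+seed)."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(df.attrs.get("metadata", {}), indent=2, sort_keys=True))
    return sidecar
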