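"""German Diabetes Risk Score (GDRS) computation.

The GDRS (updated, simplified categorical version) predicts the 5-year
risk of developing type 2 diabetes from non-invasively assessed factors:
age, waist circumference, body height, prevalent hypertension, smoking,
physical activity, coffee consumption, whole grain intake, red meat
intake and family history of diabetes.  Each factor is mapped to an
integer point value by a categorical point table; the total ranges from
0 to 122 points.  Waist circumference, not assessed in telephone
interviews, is estimated from self-reported height, weight and age with
separate linear equations per sex.

Risk-communication bands on the total score: < 46 points = low risk
(< 2% 5-year risk), 46-56 = still low (~2-5%), 57-63 = elevated
(~6-10%), > 63 = high (> 10%).  Fractional (model-predicted) scores are
classified without rounding; the bands partition [0, 122] as
[0, 46), [46, 56], (56, 63], (63, 122].

The packaged point table and waist equations are synthetic stand-ins
(see ``data/*_synthetic.json``): they reproduce the published structure
and score range but not the published point values, and are overridable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GdrsPointTable", "WaistEstimationModel", "GdrsResult",
    "load_default_point_table", "load_default_waist_model",
    "estimate_waist", "score", "classify_risk", "GdrsScorer",
    "RISK_BANDS",
]

#: (category, inclusive-exclusive description, approximate 5-year risk)
RISK_BANDS = {
    "low": "<2%",
    "still_low": "2-5%",
    "elevated": "6-10%",
    "high": ">10%",
}

GDRS_MIN, GDRS_MAX = 0.0, 122.0


class UnknownCategoryError(ValueError):
    """A component value matched no category of the point table."""


@dataclass(frozen=True)
class GdrsPointTable:
    """Categorical point assignments per GDRS component.

    ``components`` maps a component name to a dict with ``type``
    ("numeric" or "categorical") and ``categories``.  Numeric categories
    are half-open intervals [min, max) (the last interval is closed at
    the domain's upper edge) that must partition the declared domain;
    categorical ones are label -> points.
    """

    components: dict
    max_total: int = 122
    provenance: str = ""
    name: str = "custom"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.components:
            raise ValueError("point table has no components")
        max_sum = 0
        min_sum = 0
        for comp, spec in self.components.items():
            cats = spec.get("categories", [])
            if not cats:
                raise ValueError(f"component {comp!r} has no categories")
            pts = [c["points"] for c in cats]
            max_sum += max(pts)
            min_sum += min(pts)
            if spec["type"] == "numeric":
                lo, hi = spec["domain"]
                edges = sorted((c["min"], c["max"]) for c in cats)
                if edges[0][0] != lo or edges[-1][1] != hi:
                    raise ValueError(f"component {comp!r}: categories do not cover domain")
                for (a, b), (c, d) in zip(edges, edges[1:]):
                    if b != c:
                        raise ValueError(f"component {comp!r}: categories do not partition domain")
            else:
                labels = [c["label"] for c in cats]
                if len(set(labels)) != len(labels):
                    raise ValueError(f"component {comp!r}: duplicate category labels")
        if max_sum != self.max_total:
            raise ValueError(
                f"component maxima sum to {max_sum}, expected max_total={self.max_total}"
            )
        if min_sum != 0:
            raise ValueError(f"component minima sum to {min_sum}, expected 0")

    def lookup(self, component: str, value) -> tuple[int, str]:
        """Return (points, category label) for a component value."""
        spec = self.components[component]
        if spec["type"] == "numeric":
            v = float(value)
            lo, hi = spec["domain"]
            if not (lo <= v <= hi):
                raise UnknownCategoryError(
                    f"{component}={v!r} outside the table domain [{lo}, {hi}]"
                )
            for c in spec["categories"]:
                if c["min"] <= v < c["max"] or (v == hi and c["max"] == hi):
                    return int(c["points"]), c["label"]
            raise UnknownCategoryError(f"{component}={v!r} matched no category")
        label = _normalize_label(value)
        for c in spec["categories"]:
            if c["label"] == label:
                return int(c["points"]), c["label"]
        raise UnknownCategoryError(
            f"{component}={value!r} is not a known category "
            f"({[c['label'] for c in spec['categories']]})"
        )


def _normalize_label(value) -> str:
    """Map survey-style values onto point-table labels (booleans -> yes/no)."""
    if isinstance(value, (bool, np.bool_)):
        return "yes" if value else "no"
    return str(value)


@dataclass(frozen=True)
class WaistEstimationModel:
    """Sex-specific linear predictors of waist circumference (cm).

    ``coefficients[sex]`` holds intercept and slopes for height_cm,
    weight_kg and age; ``bounds`` declares the plausible adult input
    domain over which predictions are validated to be strictly positive.
    """

    coefficients: dict
    bounds: dict
    provenance: str = ""
    name: str = "custom"

    def estimate(self, sex: str, height_cm: float, weight_kg: float, age: float) -> float:
        if sex not in self.coefficients:
            raise ValueError(f"unknown sex {sex!r}; expected one of {sorted(self.coefficients)}")
        for name, value in (("height_cm", height_cm), ("weight_kg", weight_kg), ("age", age)):
            lo, hi = self.bounds[name]
            if not (lo <= float(value) <= hi):
                raise ValueError(
                    f"{name}={value!r} outside the plausible bounds [{lo}, {hi}] "
                    f"declared by the waist model"
                )
        c = self.coefficients[sex]
        return float(
            c["intercept"]
            + c["height_cm"] * height_cm
            + c["weight_kg"] * weight_kg
            + c["age"] * age
        )


@dataclass
class GdrsResult:
    """Outcome of scoring one respondent."""

    scoreable: bool
    total_points: float | None = None
    per_component_points: dict = field(default_factory=dict)
    risk_category: str | None = None
    risk_band_label: str | None = None
    missing_components: list = field(default_factory=list)
    waist_cm: float | None = None


def _load_packaged(fname: str) -> dict:
    return json.loads(resources.files("maihda.data").joinpath(fname).read_text())


def load_default_point_table() -> GdrsPointTable:
    """The packaged (synthetic stand-in) point table."""
    raw = _load_packaged("gdrs_points_synthetic.json")
    return GdrsPointTable(
        components=raw["components"], max_total=raw["max_total"],
        provenance=raw["provenance"], name=raw["name"],
    )


def load_point_table(path: str | Path) -> GdrsPointTable:
    raw = json.loads(Path(path).read_text())
    return GdrsPointTable(
        components=raw["components"], max_total=raw.get("max_total", 122),
        provenance=raw.get("provenance", ""), name=raw.get("name", str(path)),
    )


def load_default_waist_model() -> WaistEstimationModel:
    """The packaged (synthetic stand-in) waist-estimation equations."""
    raw = _load_packaged("waist_model_synthetic.json")
    return WaistEstimationModel(
        coefficients=raw["coefficients"], bounds=raw["bounds"],
        provenance=raw["provenance"], name=raw["name"],
    )


def load_waist_model(path: str | Path) -> WaistEstimationModel:
    raw = json.loads(Path(path).read_text())
    return WaistEstimationModel(
        coefficients=raw["coefficients"], bounds=raw["bounds"],
        provenance=raw.get("provenance", ""), name=raw.get("name", str(path)),
    )


def estimate_waist(sex, height_cm, weight_kg, age, model: WaistEstimationModel | None = None) -> float:
    """Estimate waist circumference (cm) from height, weight and age."""
    if model is None:
        model = load_default_waist_model()
    return model.estimate(sex, height_cm, weight_kg, age)


#: record fields feeding the scorer; waist is derived, not an input column
_SCORED_FIELDS = (
    "age", "height_cm", "hypertension", "smoking", "physical_activity_5h",
    "coffee_cups_per_day", "wholegrain_portions_per_day", "red_meat",
    "family_history",
)
_WAIST_INPUTS = ("sex_gender", "height_cm", "weight_kg", "age")


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v)


def score(
    record,
    table: GdrsPointTable | None = None,
    waist_model: WaistEstimationModel | None = None,
) -> GdrsResult:
    """Score one respondent record (mapping or Series) on the GDRS.

    Missing components yield ``scoreable=False`` (not an exception),
    mirroring survey exclusions for incomplete risk-factor data; an
    unknown category value raises :class:`UnknownCategoryError` naming
    the component and value.
    """
    if table is None:
        table = load_default_point_table()
    if waist_model is None:
        waist_model = load_default_waist_model()

    missing = [f for f in set(_SCORED_FIELDS) | set(_WAIST_INPUTS) if _is_missing(record.get(f))]
    if missing:
        return GdrsResult(scoreable=False, missing_components=sorted(missing))

    waist = waist_model.estimate(
        record["sex_gender"], float(record["height_cm"]),
        float(record["weight_kg"]), float(record["age"]),
    )
    per_component = {}
    for comp in table.components:
        value = waist if comp == "waist_cm" else record[comp]
        pts, _label = table.lookup(comp, value)
        per_component[comp] = pts
    total = float(sum(per_component.values()))
    cat = classify_risk(total)
    return GdrsResult(
        scoreable=True, total_points=total, per_component_points=per_component,
        risk_category=cat, risk_band_label=RISK_BANDS[cat],
        waist_cm=waist,
    )


def classify_risk(total_points: float) -> str:
    """Map a GDRS total to its risk-communication category.

    ``< 46`` low, ``46-56`` still low, ``(56, 63]`` elevated, ``> 63``
    high.  Fractional scores are classified without rounding.
    """
    t = float(total_points)
    if not (GDRS_MIN <= t <= GDRS_MAX):
        raise ValueError(f"GDRS total {t} outside the valid range [0, 122]")
    if t < 46:
        return "low"
    if t <= 56:
        return "still_low"
    if t <= 63:
        return "elevated"
    return "high"


class GdrsScorer(TransformerMixin, BaseEstimator):
    """Transformer appending GDRS columns to a respondent frame.

    Adds ``waist_cm_est``, ``gdrs_points``, ``gdrs_scoreable`` and
    ``risk_category``.  Records with a non-missing ``gdrs_direct`` column
    (outcome-level synthetic data) pass it through as the score without
    component scoring.

    Parameters
    ----------
    point_table, waist_model
        Override the packaged defaults (paths or loaded objects).
    """

    def __init__(self, point_table=None, waist_model=None):
        self.point_table = point_table
        self.waist_model = waist_model

    def fit(self, X=None, y=None):
        pt, wm = self.point_table, self.waist_model
        if pt is None:
            pt = load_default_point_table()
        elif not isinstance(pt, GdrsPointTable):
            pt = load_point_table(pt)
        if wm is None:
            wm = load_default_waist_model()
        elif not isinstance(wm, WaistEstimationModel):
            wm = load_waist_model(wm)
        self.point_table_ = pt
        self.waist_model_ = wm
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "point_table_"):
            self.fit(X)
        out = X.copy()
        direct = out["gdrs_direct"] if "gdrs_direct" in out else pd.Series(np.nan, index=out.index)
        totals, scoreable, cats, waists = [], [], [], []
        for idx, row in out.iterrows():
            if not _is_missing(direct.loc[idx]):
                t = float(direct.loc[idx])
                totals.append(t)
                scoreable.append(True)
                cats.append(classify_risk(t) if GDRS_MIN <= t <= GDRS_MAX else None)
                waists.append(np.nan)
                continue
            res = score(row, self.point_table_, self.waist_model_)
            scoreable.append(res.scoreable)
            totals.append(res.total_points if res.scoreable else np.nan)
            cats.append(res.risk_category)
            waists.append(res.waist_cm if res.scoreable else np.nan)
        out["waist_cm_est"] = waists
        out["gdrs_points"] = totals
        out["gdrs_scoreable"] = scoreable
        out["risk_category"] = cats
        return out
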