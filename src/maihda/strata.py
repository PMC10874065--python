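"""Intersectional strata: cross-classification of social dimensions.

Individuals are nested in strata formed by the full Cartesian product of
the categories of a small set of social dimensions.  The packaged default
is sex/gender (female, male) x educational level (CASMIN collapsed to
high, middle, low) x history of migration (no, yes; defined as having at
least one parent not born in Germany), giving 2 x 3 x 2 = 12 strata.

Stratum ids are assigned in ``itertools.product`` order over the dimensions
as given (last dimension fastest-varying), starting at 1.  This ordering is
a package convention and is stable under any reordering of the input rows.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Default social dimensions (dimension name -> ordered category labels).
DEFAULT_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "sex_gender": ("female", "male"),
    "education": ("high", "middle", "low"),
    "migration": ("no", "yes"),
}

#: Strata smaller than this trigger a logged warning (multilevel shrinkage
#: tolerates small cells, but estimates for them are imprecise).
DEFAULT_SMALL_CELL_THRESHOLD = 20


@dataclass(frozen=True)
class StratumDefinition:
    """One cell of the cross-classification."""

    stratum_id: int
    categories: tuple[tuple[str, str], ...]  # ((dimension, category), ...)
    label: str = field(compare=False, default="")

    @property
    def category_dict(self) -> dict[str, str]:
        return dict(self.categories)


def build_strata(dimensions: dict[str, tuple[str, ...]] | None = None) -> list[StratumDefinition]:
    """Construct the full cross-classification of the given dimensions.

    Parameters
    ----------
    dimensions
        Mapping of dimension name to its ordered category labels.  Every
        dimension needs at least two distinct categories.  Defaults to
        sex/gender x education x migration (12 strata).

    Returns
    -------
    list of :class:`StratumDefinition` with stable ids 1..K in
    ``itertools.product`` order (last dimension fastest-varying).
    """
    dims = DEFAULT_DIMENSIONS if dimensions is None else dimensions
    if not dims:
        raise ValueError("at least one dimension is required")
    for name, cats in dims.items():
        cats = tuple(cats)
        if len(cats) < 2:
            raise ValueError(f"dimension {name!r} needs >=2 categories, got {len(cats)}")
        if len(set(cats)) != len(cats):
            raise ValueError(f"dimension {name!r} has duplicate category names: {cats}")
    names = list(dims)
    strata = []
    def _part(name: str, cat: str) -> str:
        if name == "sex_gender":
            return {"female": "women", "male": "men"}.get(cat, cat)
        if name == "migration":
            return "history of migration" if cat == "yes" else "no history of migration"
        return f"{cat} {name}"

    for i, combo in enumerate(itertools.product(*(dims[n] for n in names)), start=1):
        cats = tuple(zip(names, combo))
        label = ", ".join(_part(n, c) for n, c in cats)
        strata.append(StratumDefinition(stratum_id=i, categories=cats, label=label))
    return strata


def strata_table(strata: list[StratumDefinition], sizes: pd.Series | None = None) -> pd.DataFrame:
    """Strata definitions as a DataFrame (exportable to CSV)."""
    rows = []
    for s in strata:
        row = {"stratum_id": s.stratum_id, **s.category_dict, "label": s.label}
        if sizes is not None:
            row["n"] = int(sizes.get(s.stratum_id, 0))
        rows.append(row)
    return pd.DataFrame(rows)


def assign(
    records: pd.DataFrame,
    strata: list[StratumDefinition] | None = None,
    small_cell_threshold: int = DEFAULT_SMALL_CELL_THRESHOLD,
) -> tuple[pd.Series, pd.Series]:
    """Map each record to exactly one stratum.

    Records must have non-missing values in every stratum-defining column
    (apply the exclusion filter upstream).

    Returns
    -------
    (stratum_id, sizes)
        ``stratum_id``: Series aligned with ``records``;
        ``sizes``: per-stratum counts indexed by stratum_id (all strata,
        including empty ones).

    Raises
    ------
    ValueError
        If any record carries a category value not present in the strata
        definitions (offending row labels are listed).
    """
    if strata is None:
        strata = build_strata()
    dim_names = [n for n, _ in strata[0].categories]
    lookup = {tuple(s.category_dict[n] for n in dim_names): s.stratum_id for s in strata}

    if records.empty:
        warnings.warn("assigning an empty record set: all stratum sizes are 0")
        sizes = pd.Series(0, index=[s.stratum_id for s in strata], name="n")
        sizes.index.name = "stratum_id"
        return pd.Series([], dtype=int, name="stratum_id"), sizes

    keys = list(map(tuple, records[dim_names].astype(object).to_numpy()))
    ids = [lookup.get(k, -1) for k in keys]
    assigned = pd.Series(ids, index=records.index, name="stratum_id")
    bad = assigned.index[assigned == -1]
    if len(bad):
        sample = records.loc[bad[:5], dim_names].to_dict("index")
        raise ValueError(
            f"{len(bad)} record(s) carry category values outside the strata "
            f"definitions; offending rows (first 5): {sample}"
        )
    sizes = assigned.value_counts().reindex([s.stratum_id for s in strata], fill_value=0)
    sizes.name = "n"
    sizes.index.name = "stratum_id"
    small = sizes[(sizes > 0) & (sizes < small_cell_threshold)]
    if len(small):
        logger.warning(
            "strata below the small-cell threshold (%d): %s",
            small_cell_threshold,
            dict(small),
        )
    return assigned, sizes


class StratumAssigner(TransformerMixin, BaseEstimator):
    """Transformer appending a ``stratum_id`` column to a records frame.

    Parameters
    ----------
    dimensions : dict or None
        As in :func:`build_strata`; None means the 12-stratum default.
    small_cell_threshold : int
        Per-stratum size below which a warning is logged.
    """

    def __init__(self, dimensions=None, small_cell_threshold=DEFAULT_SMALL_CELL_THRESHOLD):
        self.dimensions = dimensions
        self.small_cell_threshold = small_cell_threshold

    def fit(self, X: pd.DataFrame, y=None):
        self.strata_ = build_strata(self.dimensions)
        self.n_strata_ = len(self.strata_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "strata_"):
            self.fit(X)
        ids, sizes = assign(X, self.strata_, self.small_cell_threshold)
        self.sizes_ = sizes
        out = X.copy()
        out["stratum_id"] = ids
        return out
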