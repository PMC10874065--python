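"""Survey-weight rescaling and weighted descriptive statistics.

Telephone-survey weights compensate for unequal selection and response
probabilities (raking to official population margins happens upstream and
is out of scope here; weights arrive as a positive column).  For multilevel
estimation the weights are rescaled so that they sum to the number of
records -- each weight is divided by the mean weight -- which preserves
weight ratios and keeps the effective sample size interpretable.  The
rescaled weights enter the REML objective as individual-level
precision/frequency-style weights.
"""
from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["rescale", "register_rescaling", "weighted_descriptives", "RESCALING_METHODS"]


def _rescale_mean_one(w: np.ndarray) -> np.ndarray:
    return w / w.mean()


#: Registry of rescaling methods (name -> callable on a positive 1-d array).
RESCALING_METHODS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean_one": _rescale_mean_one,
}


def register_rescaling(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an alternative weight-rescaling method under ``name``."""
    RESCALING_METHODS[name] = fn


def rescale(raw_weights, method: str = "mean_one") -> np.ndarray:
    """Rescale raw survey weights for model estimation.

    The default ``mean_one`` method divides each weight by the mean weight,
    so the rescaled weights sum to the number of records; ratios between
    weights are unchanged and the operation is idempotent.

    Raises
    ------
    ValueError
        On non-positive weights or an unknown method name.
    """
    w = np.asarray(raw_weights, dtype=float)
    if w.ndim != 1:
        w = w.ravel()
    if w.size == 0:
        raise ValueError("empty weight vector")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("survey weights must all be positive and finite")
    try:
        fn = RESCALING_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown rescaling method {method!r}; known: {sorted(RESCALING_METHODS)}"
        ) from None
    return fn(w)


def weighted_descriptives(
    records: pd.DataFrame,
    weights,
    numeric: tuple[str, ...] = ("age",),
    categorical: tuple[str, ...] = ("sex_gender", "migration", "education"),
) -> pd.DataFrame:
    """Survey-style descriptive table: weighted means/SDs and percentages.

    Sample sizes ``n`` are unweighted counts; means, SDs and percentages
    use the supplied weights.  Variables that are entirely missing are
    omitted with a warning.

    Returns a tidy frame with columns
    ``variable, level, n, weighted_mean, weighted_sd, weighted_pct``.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(records):
        raise ValueError("weights are not aligned with records")
    rows = []
    for col in numeric:
        x = pd.to_numeric(records[col], errors="coerce")
        mask = x.notna().to_numpy()
        if not mask.any():
            warnings.warn(f"variable {col!r} is entirely missing; omitted")
            continue
        xv, wv = x.to_numpy()[mask], w[mask]
        mean = np.average(xv, weights=wv)
        sd = np.sqrt(np.average((xv - mean) ** 2, weights=wv))
        rows.append(
            {"variable": col, "level": "", "n": int(mask.sum()),
             "weighted_mean": mean, "weighted_sd": sd, "weighted_pct": np.nan}
        )
    for col in categorical:
        x = records[col]
        mask = x.notna().to_numpy()
        if not mask.any():
            warnings.warn(f"variable {col!r} is entirely missing; omitted")
            continue
        xv, wv = x[mask], w[mask]
        total = wv.sum()
        for level, grp in pd.Series(wv, index=xv.index).groupby(xv, observed=True):
            rows.append(
                {"variable": col, "level": str(level), "n": int((xv == level).sum()),
                 "weighted_mean": np.nan, "weighted_sd": np.nan,
                 "weighted_pct": 100.0 * grp.sum() / total}
            )
    return pd.DataFrame(rows)
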