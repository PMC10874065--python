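"""Full analysis pipeline: filter -> score -> stratify -> weight -> fit -> report.

Reproduces the survey analysis end-to-end from a records CSV (or a
synthetic population generated on the fly): exclusion accounting in the
published order (social-dimension missingness first, then unscoreable
GDRS, percentages on the pre-exclusion denominator), descriptive
Table-1-style summaries, null-model stratum predictions (Table-2-style),
fixed effects and variance measures (Table-3-style), caterpillar-plot
residual data, the age-adjusted sensitivity comparison, and one
machine-readable results JSON.  A run is reproducible from config +
input + seed; the results JSON is byte-identical across reruns.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, gdrs, strata, weights
from .model import MaihdaAnalysis, run_sensitivity_age

__all__ = ["PipelineConfig", "run_pipeline", "filter_records"]


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    input_csv: str | None = None          # if None, generate synthetically
    output_dir: str = "maihda_report"
    synthetic_mode: str = "component"     # generator mode when input_csv is None
    synthetic_effects: str = "random"     # stratum effects: fresh draws or pinned
    preexclusion: bool = True             # pad to the pre-exclusion total first
    n_missing_social: int = datasets.STUDY_N_MISSING_SOCIAL
    n_missing_components: int = datasets.STUDY_N_MISSING_COMPONENTS
    weight_col: str | None = "survey_weight"
    weight_method: str = "mean_one"
    point_table: str | None = None        # path overriding the packaged table
    waist_model: str | None = None
    small_cell_threshold: int = strata.DEFAULT_SMALL_CELL_THRESHOLD
    n_boot: int = 1000
    seed: int = 0
    decimals: int = 2
    run_sensitivity: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def filter_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion rules in the published order.

    1. drop records missing any stratum dimension (sex/gender, education,
       migration);
    2. of the remainder, drop records whose GDRS cannot be computed
       (``gdrs_scoreable`` False or missing score).

    Percentages use the pre-exclusion denominator.  Returns the analysis
    frame and the accounting dict (counts always reconcile:
    n_input - excluded = n_analyzed).
    """
    n_input = len(df)
    social_missing = df[["sex_gender", "education", "migration"]].isna().any(axis=1)
    stage1 = df.loc[~social_missing]
    if "gdrs_scoreable" in stage1:
        unscoreable = ~stage1["gdrs_scoreable"].astype(bool) | stage1["gdrs_points"].isna()
    else:
        unscoreable = stage1["gdrs_points"].isna()
    analyzed = stage1.loc[~unscoreable]
    acct = {
        "n_input": int(n_input),
        "n_missing_social": int(social_missing.sum()),
        "pct_missing_social": round(100.0 * social_missing.sum() / n_input, 2),
        "n_unscoreable": int(unscoreable.sum()),
        "pct_unscoreable": round(100.0 * unscoreable.sum() / n_input, 2),
        "n_analyzed": int(len(analyzed)),
    }
    assert acct["n_input"] - acct["n_missing_social"] - acct["n_unscoreable"] == acct["n_analyzed"]
    return analyzed, acct


def _round_df(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(decimals)
    return out


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; writes CSV tables plus results.json.

    Returns the report bundle as a dict (the same content as the files).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- input stage
    if config.input_csv is not None:
        df = pd.read_csv(config.input_csv)
    else:
        sizes = dict(datasets.STUDY_STRATUM_SIZES)
        if config.preexclusion:
            sizes = datasets.pad_stratum_sizes(sizes, datasets.STUDY_N_PREEXCLUSION)
        pc = datasets.PopulationConfig(
            stratum_sizes=sizes, seed=config.seed,
            mode=config.synthetic_mode,
            stratum_effect_mode=config.synthetic_effects,
            n_missing_social=config.n_missing_social,
            n_missing_components=config.n_missing_components,
        )
        if config.synthetic_mode == "component":
            df = datasets.generate_component_level(pc)
        else:
            df = datasets.generate_outcome_level(pc)
        df = datasets.inject_missingness(
            df, config.n_missing_social, config.n_missing_components, seed=config.seed
        )
        datasets.write_dataset(df, outdir / "synthetic_input.csv")

    # --- score stage (adds gdrs_points / gdrs_scoreable)
    scorer = gdrs.GdrsScorer(config.point_table, config.waist_model).fit()
    scored = scorer.transform(df)

    # --- exclusion stage
    analyzed, exclusions = filter_records(scored)

    # --- stratify
    assigner = strata.StratumAssigner(small_cell_threshold=config.small_cell_threshold).fit(analyzed)
    analyzed = assigner.transform(analyzed)
    strata_csv = strata.strata_table(assigner.strata_, assigner.sizes_)

    # --- weights + descriptives
    w = None
    if config.weight_col is not None and config.weight_col in analyzed:
        w = weights.rescale(analyzed[config.weight_col].to_numpy(), config.weight_method)
    table1 = weights.weighted_descriptives(
        analyzed, w if w is not None else np.ones(len(analyzed))
    )

    # --- models and measures
    analysis = MaihdaAnalysis(
        weight_col=config.weight_col if w is not None else None,
        rescale_method=config.weight_method,
        n_boot=config.n_boot, random_state=config.seed,
    ).fit(analyzed)
    table2 = analysis.stratum_predictions("model1_total")
    table2 = table2.merge(
        strata_csv[["stratum_id", "label"]], on="stratum_id", how="left"
    )
    residuals = analysis.stratum_residuals()
    fe = analysis.model2_.fe_confint().reset_index(names="term")
    var_ci_1 = analysis.variance_component_cis("model1")
    var_ci_2 = analysis.variance_component_cis("model2")
    decomp = analysis.decomposition_.as_percent()

    sensitivity = None
    if config.run_sensitivity:
        sens = run_sensitivity_age(
            analyzed,
            weight_col=config.weight_col if w is not None else None,
            rescale_method=config.weight_method,
            n_boot=config.n_boot, random_state=config.seed,
        )
        sensitivity = sens["comparison"]

    d = config.decimals
    results = {
        "config": dataclasses.asdict(config),
        "exclusions": exclusions,
        "variance_decomposition": decomp,
        "model1": {
            "intercept": analysis.model1_.intercept_,
            "sigma_u2": analysis.model1_.sigma_u2_,
            "sigma_e2": analysis.model1_.sigma_e2_,
            "sigma_u2_ci95": var_ci_1["sigma_u2"],
            "sigma_e2_ci95": var_ci_1["sigma_e2"],
            "converged": analysis.model1_.converged_,
        },
        "model2": {
            "fixed_effects": {
                row["term"]: {"estimate": row["estimate"], "lo": row["lo"], "hi": row["hi"]}
                for row in fe.to_dict("records")
            },
            "sigma_u2": analysis.model2_.sigma_u2_,
            "sigma_e2": analysis.model2_.sigma_e2_,
            "sigma_u2_ci95": var_ci_2["sigma_u2"],
            "sigma_e2_ci95": var_ci_2["sigma_e2"],
            "converged": analysis.model2_.converged_,
        },
        "stratum_predictions_model1": table2.drop(columns="basis").to_dict("records"),
        "stratum_residuals": residuals.to_dict("records"),
        "sensitivity_age": sensitivity.to_dict("records") if sensitivity is not None else None,
        "seeds": {"seed": config.seed, "n_boot": config.n_boot},
    }
    results = _jsonify(results)

    _round_df(table1, d).to_csv(outdir / "table1_descriptives.csv", index=False)
    _round_df(table2, d).to_csv(outdir / "table2_stratum_predictions.csv", index=False)
    _round_df(fe, d).to_csv(outdir / "table3_fixed_effects.csv", index=False)
    _round_df(residuals, d).to_csv(outdir / "caterpillar_residuals.csv", index=False)
    strata_csv.to_csv(outdir / "strata.csv", index=False)
    if sensitivity is not None:
        _round_df(sensitivity, d).to_csv(outdir / "sensitivity_age.csv", index=False)
    (outdir / "exclusions.json").write_text(json.dumps(exclusions, indent=2, sort_keys=True))
    (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))

    results["_tables"] = {
        "table1": table1, "table2": table2, "fixed_effects": fe,
        "residuals": residuals, "strata": strata_csv, "sensitivity": sensitivity,
    }
    results["_analysis"] = analysis
    return results
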