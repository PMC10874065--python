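"""Synthetic survey generator: structure, determinism, missingness."""
import numpy as np
import pandas as pd
import pytest

from maihda.datasets import (
    STUDY_N_PREEXCLUSION,
    STUDY_STRATUM_MEANS,
    STUDY_STRATUM_SIZES,
    PopulationConfig,
    generate_component_level,
    generate_outcome_level,
    inject_missingness,
    pad_stratum_sizes,
    write_dataset,
)
from maihda.gdrs import GdrsScorer, load_default_point_table
from maihda.pipeline import filter_records


def test_default_config_generates_analysis_sample_size():
    df = generate_outcome_level(PopulationConfig(seed=0))
    assert len(df) == 2253
    assert df["gdrs_direct"].notna().all()


def test_degenerate_variances_give_constant_outcome():
    cfg = PopulationConfig(seed=0, between_var=0.0, within_var=0.0, grand_mean=38.98)
    df = generate_outcome_level(cfg)
    assert np.allclose(df["gdrs_direct"], 38.98)


def test_same_seed_identical_different_seed_distinct(tmp_path):
    a = generate_outcome_level(PopulationConfig(seed=5))
    b = generate_outcome_level(PopulationConfig(seed=5))
    c = generate_outcome_level(PopulationConfig(seed=6))
    pd.testing.assert_frame_equal(a, b)
    assert not np.allclose(a["gdrs_direct"], c["gdrs_direct"])
    # byte-identical CSV on re-run
    write_dataset(a, tmp_path / "a.csv")
    write_dataset(b, tmp_path / "b.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_fixed_stratum_effects_reproduce_pinned_means():
    cfg = PopulationConfig(seed=0, stratum_effect_mode="fixed", within_var=0.0)
    df = generate_outcome_level(cfg)
    means = df.groupby(["sex_gender", "education", "migration"])["gdrs_direct"].mean()
    for key, mu in STUDY_STRATUM_MEANS.items():
        assert np.isclose(means.loc[key], mu)


def test_unknown_fixed_effect_name_rejected():
    with pytest.raises(ValueError, match="unknown fixed-effect"):
        PopulationConfig(fixed_effects={"intercept": 36.0, "beta_typo": 1.0})


def test_invalid_sizes_and_variances_rejected():
    with pytest.raises(ValueError, match="> 0"):
        PopulationConfig(stratum_sizes={("male", "low", "yes"): 0})
    with pytest.raises(ValueError, match=">= 0"):
        PopulationConfig(between_var=-1.0)


def test_between_and_within_variance_recovered_empirically():
    """Across replicates, the variance of simulated stratum means is
    between_var + within_var/n, and the pooled within-stratum variance is
    within_var."""
    bv, wv, m = 25.0, 100.0, 40
    sizes = {k: m for k in STUDY_STRATUM_SIZES}
    means, withins = [], []
    for seed in range(150):
        df = generate_outcome_level(
            PopulationConfig(stratum_sizes=sizes, between_var=bv, within_var=wv, seed=seed)
        )
        g = df.groupby(["sex_gender", "education", "migration"])["gdrs_direct"]
        means.extend(g.mean().to_numpy())
        withins.extend(g.var(ddof=1).to_numpy())
    assert np.var(means, ddof=1) == pytest.approx(bv + wv / m, rel=0.12)
    assert np.mean(withins) == pytest.approx(wv, rel=0.05)


def test_component_level_records_all_scoreable_and_adult():
    cfg = PopulationConfig(seed=11, mode="component",
                           stratum_sizes={k: max(2, v // 10) for k, v in STUDY_STRATUM_SIZES.items()})
    df = generate_component_level(cfg, load_default_point_table())
    assert (df["age"] >= 18).all()
    scored = GdrsScorer().fit().transform(df)
    assert scored["gdrs_scoreable"].all()
    assert scored["gdrs_points"].between(0, 122).all()
    # metadata documents the fixture distributions
    assert "component_distributions" in df.attrs["metadata"]


def test_component_level_deterministic():
    cfg = dict(seed=3, mode="component",
               stratum_sizes={k: 5 for k in STUDY_STRATUM_SIZES},
               n_missing_social=0, n_missing_components=0)
    a = generate_component_level(PopulationConfig(**cfg))
    b = generate_component_level(PopulationConfig(**cfg))
    pd.testing.assert_frame_equal(a, b)


# -- missingness ------------------------------------------------------------


def _preexclusion_outcome(seed=0):
    sizes = pad_stratum_sizes(dict(STUDY_STRATUM_SIZES), STUDY_N_PREEXCLUSION)
    return generate_outcome_level(PopulationConfig(stratum_sizes=sizes, seed=seed))


def test_exact_missing_counts_and_disjoint_sets():
    df = _preexclusion_outcome()
    out = inject_missingness(df, 7, 67, seed=1)
    social = out[["education", "migration"]].isna().any(axis=1)
    comp = out["gdrs_direct"].isna()
    assert int(social.sum()) == 7
    assert int(comp.sum()) == 67
    assert int((social & comp).sum()) == 0
    assert comp.sum() / len(out) == pytest.approx(67 / 2327, abs=1e-12)  # 2.88%


def test_exclusion_filter_retains_published_analysis_n():
    df = _preexclusion_outcome()
    assert len(df) == 2327
    out = inject_missingness(df, 7, 67, seed=1)
    scored = GdrsScorer().fit().transform(out)
    analyzed, acct = filter_records(scored)
    assert acct["n_analyzed"] == 2253
    assert acct["pct_missing_social"] == 0.30
    assert acct["pct_unscoreable"] == 2.88


def test_zero_missingness_is_identity_for_filter():
    df = generate_outcome_level(PopulationConfig(seed=2))
    out = inject_missingness(df, 0, 0, seed=0)
    scored = GdrsScorer().fit().transform(out)
    analyzed, acct = filter_records(scored)
    assert acct["n_analyzed"] == len(df)


def test_excessive_missingness_rejected():
    df = generate_outcome_level(
        PopulationConfig(seed=0, stratum_sizes={k: 2 for k in STUDY_STRATUM_SIZES},
                         n_missing_social=0, n_missing_components=0)
    )
    with pytest.raises(ValueError, match="exceeds"):
        inject_missingness(df, 20, 10, seed=0)


def test_component_level_missingness_blanks_score_components():
    cfg = PopulationConfig(seed=4, mode="component",
                           stratum_sizes={k: 10 for k in STUDY_STRATUM_SIZES})
    df = generate_component_level(cfg)
    out = inject_missingness(df, 3, 9, seed=4)
    scored = GdrsScorer().fit().transform(out)
    analyzed, acct = filter_records(scored)
    assert acct["n_missing_social"] == 3
    assert acct["n_unscoreable"] == 9
    assert acct["n_analyzed"] == 120 - 12
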