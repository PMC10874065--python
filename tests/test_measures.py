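"""MAIHDA measures: VPC, PCV, stratum predictions, residuals, sensitivity."""
import numpy as np
import pandas as pd
import pytest

from maihda.datasets import (
    STUDY_FIXED_EFFECTS,
    STUDY_STRATUM_SIZES,
    PopulationConfig,
    generate_outcome_level,
)
from maihda.model import (
    MaihdaAnalysis,
    RandomInterceptREML,
    pcv_from_components,
    run_sensitivity_age,
    vpc,
    vpc_from_components,
)
from maihda.strata import StratumAssigner


# -- VPC / PCV identities ---------------------------------------------------


@pytest.mark.parametrize("su2, se2, pct", [
    (43.79, 269.00, 14.00),  # null model components
    (8.57, 269.09, 3.09),    # main-effects model components
    (0.0, 100.0, 0.0),
])
def test_vpc_identity(su2, se2, pct):
    assert round(100 * vpc_from_components(su2, se2), 2) == pct


def test_vpc_undefined_when_total_variance_zero():
    with pytest.raises(ValueError, match="undefined"):
        vpc_from_components(0.0, 0.0)


@pytest.mark.parametrize("su1, su2, expected", [
    (10.0, 10.0, 0.0),
    (10.0, 0.0, 1.0),
    (43.79, 8.57, 0.8043),  # arithmetic on the printed components
    (10.0, 12.0, -0.2),     # adjusted model can increase the variance
])
def test_pcv_arithmetic(su1, su2, expected):
    p, omp = pcv_from_components(su1, su2)
    assert p == pytest.approx(expected, abs=5e-5)
    assert omp == pytest.approx(1 - expected, abs=5e-5)


def test_pcv_undefined_for_zero_null_variance():
    with pytest.raises(ValueError, match="undefined"):
        pcv_from_components(0.0, 1.0)


# -- full analysis on synthetic outcome data --------------------------------


@pytest.fixture(scope="module")
def analysis(study_outcome_frame_module):
    return MaihdaAnalysis(
        outcome_col="gdrs_direct", weight_col="survey_weight",
        n_boot=200, random_state=1,
    ).fit(study_outcome_frame_module)


@pytest.fixture(scope="module")
def study_outcome_frame_module():
    df = generate_outcome_level(PopulationConfig(seed=42))
    return StratumAssigner().fit(df).transform(df)


def test_decomposition_identity_total_equals_fixed_plus_residual(analysis):
    fixed = analysis.stratum_predictions("model2_fixed", n_boot=10)
    total = analysis.stratum_predictions("model2_total", n_boot=10)
    resid = analysis.stratum_residuals(n_boot=10)
    gap = total["predicted_mean"] - fixed["predicted_mean"] - resid["residual"]
    assert np.allclose(gap, 0.0, atol=1e-10)
    assert np.allclose(resid["residual"], analysis.model2_.ranef_)


def test_reference_category_invariance(study_outcome_frame_module):
    """Changing the reference categories leaves u_hat, the variance
    components and the VPC unchanged."""
    base = MaihdaAnalysis(outcome_col="gdrs_direct", n_boot=2).fit(study_outcome_frame_module)
    alt = MaihdaAnalysis(
        outcome_col="gdrs_direct", n_boot=2, reference=("male", "low", "yes")
    ).fit(study_outcome_frame_module)
    assert base.model2_.sigma_u2_ == pytest.approx(alt.model2_.sigma_u2_, rel=1e-5)
    assert base.model2_.sigma_e2_ == pytest.approx(alt.model2_.sigma_e2_, rel=1e-5)
    assert np.allclose(base.model2_.ranef_, alt.model2_.ranef_, rtol=1e-6, atol=1e-6)
    assert base.decomposition_.vpc_model2 == pytest.approx(alt.decomposition_.vpc_model2, rel=1e-5)


def test_bootstrap_deterministic_under_seed(study_outcome_frame_module):
    kw = dict(outcome_col="gdrs_direct", n_boot=50, random_state=9)
    a = MaihdaAnalysis(**kw).fit(study_outcome_frame_module).stratum_residuals()
    b = MaihdaAnalysis(**kw).fit(study_outcome_frame_module).stratum_residuals()
    pd.testing.assert_frame_equal(a, b)


def test_bootstrap_size_changes_ci_not_point(study_outcome_frame_module):
    an = MaihdaAnalysis(outcome_col="gdrs_direct", random_state=2).fit(study_outcome_frame_module)
    small = an.stratum_predictions("model1_total", n_boot=20)
    large = an.stratum_predictions("model1_total", n_boot=100)
    assert np.allclose(small["predicted_mean"], large["predicted_mean"])
    assert not np.allclose(small["ci_lo"], large["ci_lo"])


def test_bootstrap_requires_two_replicates(analysis):
    with pytest.raises(ValueError, match="B >= 2"):
        analysis.stratum_predictions(n_boot=1)


def test_zero_between_variance_residuals_exactly_zero():
    """A boundary fit (sigma_u^2 = 0) yields all-zero stratum residuals and
    every stratum prediction equal to the fixed-effect prediction."""
    rng = np.random.default_rng(0)
    df = generate_outcome_level(
        PopulationConfig(seed=1, between_var=0.0, within_var=4.0,
                         stratum_sizes={k: 40 for k in STUDY_STRATUM_SIZES})
    )
    df = StratumAssigner().fit(df).transform(df)
    an = MaihdaAnalysis(outcome_col="gdrs_direct", n_boot=20, random_state=0).fit(df)
    if an.model1_.sigma_u2_ == 0.0:
        assert np.allclose(an.model1_.ranef_, 0.0)
        pred = an.stratum_predictions("model1_total", n_boot=20)
        assert np.allclose(pred["predicted_mean"], an.model1_.intercept_)


def test_additive_data_residual_cis_cover_zero(additive_frame):
    """Purely additive generating process: no stratum's residual CI should
    (except rarely) exclude 0 -- no spurious multiplicative effects."""
    an = MaihdaAnalysis(
        outcome_col="gdrs_direct", n_boot=200, random_state=3
    ).fit(additive_frame)
    resid = an.stratum_residuals()
    covered = ((resid["ci_lo"] <= 0) & (resid["ci_hi"] >= 0)).mean()
    assert covered >= 0.9


def test_injected_interaction_detected():
    """A large multiplicative effect in one stratum is flagged: its
    residual CI excludes zero."""
    cfg = PopulationConfig(seed=21, effect_structure="main_effects", between_var=0.0)
    df = generate_outcome_level(cfg)
    target = (df["sex_gender"] == "male") & (df["education"] == "low") & (df["migration"] == "no")
    df.loc[target, "gdrs_direct"] += 15.0
    df = StratumAssigner().fit(df).transform(df)
    an = MaihdaAnalysis(outcome_col="gdrs_direct", n_boot=200, random_state=4).fit(df)
    resid = an.stratum_residuals().set_index("stratum_id")
    target_id = df.loc[target, "stratum_id"].iloc[0]
    assert resid.loc[target_id, "ci_excludes_zero"]
    assert resid.loc[target_id, "residual"] > 5.0


def test_fixed_effect_recovery_main_effects_data():
    """Mean estimates of the male and low-education effects across seeded
    replicates recover the generating coefficients."""
    betas = []
    for seed in range(40):
        cfg = PopulationConfig(seed=seed, effect_structure="main_effects", between_var=8.57)
        df = generate_outcome_level(cfg)
        df = StratumAssigner().fit(df).transform(df)
        an = MaihdaAnalysis(outcome_col="gdrs_direct", n_boot=2).fit(df)
        betas.append(dict(zip(an.model2_.fe_names_, an.model2_.fe_params_)))
    b = pd.DataFrame(betas)
    assert b["male"].mean() == pytest.approx(STUDY_FIXED_EFFECTS["male"], abs=1.5)
    assert b["education_low"].mean() == pytest.approx(STUDY_FIXED_EFFECTS["education_low"], abs=2.0)
    assert b["migration_yes"].mean() == pytest.approx(STUDY_FIXED_EFFECTS["migration"], abs=2.0)


# -- age sensitivity --------------------------------------------------------


def test_age_independent_of_outcome_leaves_vpc_unchanged(study_outcome_frame_module):
    df = study_outcome_frame_module.copy()
    df["age"] = np.random.default_rng(10).uniform(18, 90, len(df))  # pure noise
    out = run_sensitivity_age(df, outcome_col="gdrs_direct", n_boot=2)
    v_main = out["main"].decomposition_.vpc_model1
    v_age = out["age_adjusted"].decomposition_.vpc_model1
    assert v_age == pytest.approx(v_main, abs=0.01)
    assert set(out["comparison"]["analysis"]) == {"main", "age_adjusted"}


def test_age_confounding_attenuates_migration_effect():
    """When age drives the outcome and is lower among respondents with a
    migration history, the migration main effect attenuates toward zero
    once age is controlled."""
    rng = np.random.default_rng(11)
    cfg = PopulationConfig(seed=11, effect_structure="main_effects", between_var=0.0)
    df = generate_outcome_level(cfg)
    # make the outcome strongly age-driven on top of the main effects
    df["gdrs_direct"] += 0.6 * (df["age"] - df["age"].mean())
    df = StratumAssigner().fit(df).transform(df)
    out = run_sensitivity_age(df, outcome_col="gdrs_direct", n_boot=2)
    b_main = dict(zip(out["main"].model2_.fe_names_, out["main"].model2_.fe_params_))
    b_age = dict(zip(out["age_adjusted"].model2_.fe_names_, out["age_adjusted"].model2_.fe_params_))
    assert abs(b_age["migration_yes"]) < abs(b_main["migration_yes"])
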