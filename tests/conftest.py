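import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_outcome_frame():
    """One outcome-level synthetic survey (study-default sizes), stratified."""
    from maihda.datasets import PopulationConfig, generate_outcome_level
    from maihda.strata import StratumAssigner

    df = generate_outcome_level(PopulationConfig(seed=42))
    return StratumAssigner().fit(df).transform(df)


@pytest.fixture(scope="session")
def additive_frame():
    """Purely additive outcome data: main effects only, no stratum-level
    interaction variance."""
    from maihda.datasets import PopulationConfig, generate_outcome_level
    from maihda.strata import StratumAssigner

    cfg = PopulationConfig(
        seed=7, effect_structure="main_effects", between_var=0.0,
    )
    df = generate_outcome_level(cfg)
    return StratumAssigner().fit(df).transform(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def min_profile():
    """Respondent engineered to hit the 0-point category of every GDRS
    component (with the packaged synthetic table and waist model)."""
    return pd.Series({
        "sex_gender": "male", "age": 25.0, "height_cm": 190.0, "weight_kg": 60.0,
        "hypertension": False, "smoking": "never_or_former_lt20",
        "physical_activity_5h": True, "coffee_cups_per_day": 5.0,
        "wholegrain_portions_per_day": 2.5, "red_meat": "lt1_per_week",
        "family_history": "none",
    })


@pytest.fixture(scope="session")
def max_profile():
    """Respondent engineered to hit the top category of every component."""
    return pd.Series({
        "sex_gender": "male", "age": 70.0, "height_cm": 150.0, "weight_kg": 120.0,
        "hypertension": True, "smoking": "current_ge20",
        "physical_activity_5h": False, "coffee_cups_per_day": 0.0,
        "wholegrain_portions_per_day": 0.0, "red_meat": "gt1_per_day",
        "family_history": "parent_and_sibling",
    })
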