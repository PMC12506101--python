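import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bmirrda.config import StudyConfig
from bmirrda.synth import ScenarioConfig, generate, generate_reference

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def short_config() -> StudyConfig:
    return StudyConfig(study_start=dt.date(2000, 1, 1), study_end=dt.date(2009, 12, 31))


@pytest.fixture(scope="session")
def reference():
    return generate_reference()


@pytest.fixture(scope="session")
def small_dataset():
    """A modest 10-year scenario with all error types injected."""
    scenario = ScenarioConfig(
        n_persons=150, seed=11, study_start=dt.date(2000, 1, 1), study_end=dt.date(2009, 12, 31)
    )
    return generate(scenario)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    from bmirrda.harmonise import build_rrda

    return build_rrda(
        small_dataset.tables, small_dataset.codelists, small_dataset.reference, small_dataset.config
    )


def persons_frame(rows):
    """Helper: build a typed demographics frame from plain tuples."""
    df = pd.DataFrame(rows, columns=["person_id", "sex", "week_of_birth", "date_of_death", "linkage_status"])
    df["week_of_birth"] = pd.to_datetime(df["week_of_birth"])
    df["date_of_death"] = pd.to_datetime(df["date_of_death"])
    df["linkage_status"] = df["linkage_status"].astype("int64")
    return df
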