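import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wsyrnet import fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def compound_table() -> pd.DataFrame:
    return fixtures.load_compound_table()


@pytest.fixture(scope="session")
def target_table() -> pd.DataFrame:
    return fixtures.load_target_table()


@pytest.fixture(scope="session")
def deg_table() -> pd.DataFrame:
    return fixtures.load_deg_table()


@pytest.fixture(scope="session")
def docking_tables() -> dict[str, pd.DataFrame]:
    return {r: fixtures.load_docking_table(r) for r in ("ESR1", "ESR2")}
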