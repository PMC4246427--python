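import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from injspec import (
    MortalityTable,
    StandardPopulation,
    UnspecifiedCodeMap,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def codemap() -> UnspecifiedCodeMap:
    return UnspecifiedCodeMap.default()


@pytest.fixture
def std_equal() -> StandardPopulation:
    return StandardPopulation({"65+": 1.0})


def make_table(rows, age_strata=None) -> MortalityTable:
    """rows: (year, age_group, intent, cause, deaths, population) tuples."""
    df = pd.DataFrame(
        rows, columns=["year", "age_group", "intent", "cause", "deaths", "population"]
    )
    return MortalityTable.from_dataframe(df, age_strata=age_strata)


@pytest.fixture
def toy_table() -> MortalityTable:
    """One stratum, two years; year 2000 sits exactly at a 10% unspecified share."""
    pop = 100_000
    return make_table(
        [
            (1999, "65+", "unintentional", "A", 60, pop),
            (1999, "65+", "unintentional", "B", 20, pop),
            (1999, "65+", "unintentional", "unspecified", 20, pop),
            (2000, "65+", "unintentional", "A", 70, pop),
            (2000, "65+", "unintentional", "B", 20, pop),
            (2000, "65+", "unintentional", "unspecified", 10, pop),
        ],
        age_strata=("65+",),
    )
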