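import numpy as np
import pandas as pd
import pytest

from wtflari import load_fixture, make_prototype_patterns


@pytest.fixture(scope="session")
def exposure():
    return load_fixture("exposure")


@pytest.fixture(scope="session")
def contingency():
    return load_fixture("seasonal_contingency")


@pytest.fixture(scope="session")
def share_matrix():
    return load_fixture("region_wt_share")


@pytest.fixture(scope="session")
def proto4():
    """Four orthonormal prototype circulation patterns on the default grid."""
    return make_prototype_patterns(4)


@pytest.fixture()
def tiny_daily():
    """A minimal daily dataset: 8 days covering all WTs, 3 events."""
    wt = pd.DataFrame({
        "date": pd.date_range("2001-01-01", periods=8, freq="D"),
        "wt": [3, 3, 1, 2, 4, 5, 6, 7],
    })
    events = pd.DataFrame({
        "date": pd.to_datetime(["2001-01-01", "2001-01-01", "2001-01-04"]),
        "region": ["Liguria", "Campania", "Piemonte"],
        "count": [2, 1, 1],
    })
    return wt, events
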