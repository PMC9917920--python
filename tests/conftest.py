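import numpy as np
import pandas as pd
import pytest

from ibdsim.engine import CHANNELS, DemandSeries
from ibdsim.io import load_population_config
from ibdsim.pathway import PathwayParameters
from ibdsim.population import MarginalTargetSet, generate_population


@pytest.fixture(scope="session")
def tokyo_targets():
    return load_population_config("tokyo")


@pytest.fixture(scope="session")
def hokkaido_targets():
    return load_population_config("hokkaido")


@pytest.fixture(scope="session")
def small_targets():
    """A small generic region with feasible age moments and unit weights."""
    return MarginalTargetSet(
        region_name="testville",
        total_patients=2000.0,
        sex_proportions={"male": 0.5, "female": 0.5},
        condition_proportions={"UC": 0.6, "CD": 0.4},
        age_targets={(c, s): (50.0, 12.0) for c in ("UC", "CD") for s in ("male", "female")},
        initial_diagnosed_fraction=0.6,
        initial_biologic_fraction=0.2,
    )


@pytest.fixture(scope="session")
def small_population(small_targets):
    return generate_population(small_targets, 2000, seed=42)


@pytest.fixture(scope="session")
def default_params():
    return PathwayParameters()


def make_series(values_by_channel, start="2020-01-06", region=""):
    """Build a DemandSeries from per-channel weekly values (scalars or lists)."""
    lengths = [len(v) for v in values_by_channel.values() if np.ndim(v) > 0]
    n = lengths[0] if lengths else 8
    frame = pd.DataFrame({"week_start": pd.date_range(start, periods=n, freq="7D")})
    for ch in CHANNELS:
        v = values_by_channel.get(ch, 0.0)
        frame[ch] = v if np.ndim(v) > 0 else np.full(n, float(v))
    return DemandSeries(frame=frame, region=region)


@pytest.fixture
def series_factory():
    return make_series
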