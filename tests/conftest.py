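import numpy as np
import pandas as pd
import pytest

from arcticphen.synthetic import PopulationScenario, generate_tracks


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scenario():
    return PopulationScenario(
        population_id="test_pop",
        n_individuals=4,
        years=(2018, 2019, 2020),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_tracks(small_scenario):
    """Tracks, ground truth and site-years for a 4-bird, 3-year population."""
    return generate_tracks(small_scenario, np.random.default_rng(7))


def make_fixes(rows, device="GPS", individual="bird1"):
    """Build a fix table from (timestamp, lat, lon) tuples."""
    return pd.DataFrame(
        {
            "individual_id": individual,
            "timestamp": pd.to_datetime([r[0] for r in rows], utc=True),
            "lat": [r[1] for r in rows],
            "lon": [r[2] for r in rows],
            "device": device,
        }
    )
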