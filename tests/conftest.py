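import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import isoniche as iso

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

logging.getLogger("isoniche").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_population() -> iso.SyntheticPopulation:
    """One seeded population under the default study conditions."""
    return iso.simulate_population(iso.GeneratorConfig(seed=20180801))


@pytest.fixture()
def tiny_segments() -> pd.DataFrame:
    """Three individuals, three segments, hand-checkable values."""
    return pd.DataFrame(
        {
            "individual_id": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "segment_id": ["s1", "s2", "s3"] * 3,
            "d15N": [5.0, 5.0, 5.0, 1.0, 2.0, 3.0, 7.0, 8.0, 9.0],
            "d13C": [-25.0, -24.0, -26.0, -20.0, -20.0, -20.0,
                     -22.0, -23.0, -21.0],
        }
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
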