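import numpy as np
import pytest

from stressorweave import StudyFrame
from stressorweave.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_frame():
    """3 regions x 5 years: small enough for exhaustive checks."""
    return StudyFrame(regions=("SOUTH", "MID", "NORTH"), start_year=2000,
                      end_year=2004, era_break_year=2003)


@pytest.fixture(scope="session")
def default_dataset():
    """One shared desk-scale synthetic dataset (3 regions, 30 years)."""
    return generate_dataset(SimulationConfig(), seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
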