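import math

import numpy as np
import pytest

from rhomboclone import LognormalRadiusModel, SimulationConfig, simulate_null_clones


def normal_cdf(z: float) -> float:
    """Independent standard-normal CDF oracle (erfc-based, no scipy)."""
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def crossing_oracle(mu: float, sigma: float, x: float) -> float:
    """Independent oracle for the null crossing probability L(x)."""
    if x in (0.0, 1.0):
        return 1.0
    d = min(x, 1.0 - x)
    return 1.0 - normal_cdf((math.log(d) - mu) / sigma)


@pytest.fixture(scope="session")
def model() -> LognormalRadiusModel:
    return LognormalRadiusModel()  # mu=-1.34, sigma=0.64


@pytest.fixture(scope="session")
def calibrated_delta(model) -> float:
    return model.calibrate_delta(0.22)


@pytest.fixture(scope="session")
def null_table_5000():
    """One large null clone sample shared by curve-consistency tests."""
    return simulate_null_clones(SimulationConfig(n_clones=5000, seed=0))
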