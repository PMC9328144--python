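import numpy as np
import pytest

from gutsred import (
    ExposureProfile,
    ITParams,
    SDParams,
    TestDesign,
    constant_profile,
    generate_test,
)


@pytest.fixture
def sd_truth():
    return SDParams(kD=0.7, zw=2.0, bw=0.3, hb=0.01)


@pytest.fixture
def it_truth():
    return ITParams(kD=0.7, mw=4.0, beta=3.0, hb=0.01)


@pytest.fixture
def acute_design():
    return TestDesign()


@pytest.fixture
def sd_dataset(sd_truth, acute_design):
    return generate_test(sd_truth, "SD", acute_design, seed=42)


@pytest.fixture
def it_dataset(it_truth, acute_design):
    return generate_test(it_truth, "IT", acute_design, seed=42)


def random_piecewise_profile(rng, n_max=8, t_scale=2.0, c_scale=20.0):
    """Random piecewise-linear exposure profile for property tests."""
    n = int(rng.integers(2, n_max))
    times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, t_scale, n))])
    concs = rng.uniform(0.0, c_scale, n + 1)
    return ExposureProfile(times, concs)
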