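import numpy as np
import pytest
from hypothesis import settings

from scorebias.design_grid import build_design
from scorebias.datagen import generate_sample

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def condition(rsro="stronger", n=300, profile="low", k=4):
    return next(
        c
        for c in build_design()
        if c.rsro == rsro
        and c.sample_size == n
        and c.loading_profile == profile
        and c.n_items == k
    )


@pytest.fixture(scope="session")
def low4_cond():
    return condition("stronger", 300, "low", 4)


@pytest.fixture(scope="session")
def high8_cond():
    return condition("stronger", 1000, "high", 8)


@pytest.fixture(scope="session")
def low4_sample(low4_cond):
    return generate_sample(low4_cond, seed=20211015)


@pytest.fixture(scope="session")
def high8_sample(high8_cond):
    return generate_sample(high8_cond, seed=20211015)


@pytest.fixture(scope="session")
def big_high4_sample():
    """Large continuous-model sample for parameter-recovery checks."""
    cond = condition("stronger", 300, "high", 4)
    return generate_sample(cond, seed=7, n=100_000)
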