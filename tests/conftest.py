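import numpy as np
import pytest

from strlink.insert_model import (
    InsertObservation,
    InsertSizeDistribution,
    STRRegion,
    build_normalization_table,
)
from strlink.mutation import MutationParams


@pytest.fixture
def toy_region() -> STRRegion:
    """Tiny locus used throughout the worked examples: [100, 109], dimer x5."""
    return STRRegion("chr1", 100, 109, 2, 5, id="toy")


@pytest.fixture
def toy_F() -> InsertSizeDistribution:
    """Uniform pmf 0.1 on lengths 10..19 with K = 19."""
    return InsertSizeDistribution.uniform(10, 19, K=19)


@pytest.fixture
def toy_table(toy_region, toy_F):
    return build_normalization_table(toy_region, toy_F, 0, 10)


@pytest.fixture
def peaked_F() -> InsertSizeDistribution:
    """F = {14:0.1, 15:0.2, 16:0.4, 17:0.2, 18:0.1}, K = 18."""
    return InsertSizeDistribution({14: 0.1, 15: 0.2, 16: 0.4, 17: 0.2, 18: 0.1}, K=18)


@pytest.fixture
def default_F() -> InsertSizeDistribution:
    return InsertSizeDistribution.normal(350.0, 50.0, K=2000)


@pytest.fixture
def params() -> MutationParams:
    return MutationParams(mu_s=1e-3, Ne=10400.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_obs(pairs):
    """[(s, l), ...] -> observations (e = s + l)."""
    return [InsertObservation(s, s + l) for s, l in pairs]
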