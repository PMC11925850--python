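import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for naive_reference

from actifptm import (
    ChainPartition,
    FlankScenarioSpec,
    make_flank_scenario,
    make_random_bundle,
)


@pytest.fixture(scope="session")
def seed7_bundle():
    """The canonical two-chain random bundle used across oracle checks."""
    return make_random_bundle(N=10, n_chains=2, seed=7)


@pytest.fixture(scope="session")
def flank_trio():
    """Canonical flank scenario: flankless / short / long bundles."""
    return make_flank_scenario(FlankScenarioSpec(seed=0))


@pytest.fixture()
def two_chain_partition():
    return ChainPartition.from_lengths([7, 3])


def random_distance_matrix(N: int, rng: np.random.Generator, edges: np.ndarray):
    """Symmetric zero-diagonal matrix whose off-diagonal entries are bin
    midpoints — the distances a binned point mass represents exactly."""
    mids = 0.5 * (edges[:-1] + edges[1:])
    D = mids[rng.integers(0, mids.size, size=(N, N))]
    D = np.triu(D, 1)
    return D + D.T
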