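import numpy as np
import pandas as pd
import pytest

from chronet import OtuTable, SimulationConfig, simulate_dataset
from chronet.types import DistanceMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic chronosequence (30 samples, 60 families)."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_otu_table(rng):
    def _make(n_samples=6, n_taxa=12, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        counts = r.integers(0, 50, size=(n_samples, n_taxa))
        return OtuTable(pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        ))
    return _make


def euclidean_distance_matrix(points, ids=None):
    points = np.asarray(points, dtype=float)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids=ids, values=d)


@pytest.fixture()
def make_euclidean_dist():
    return euclidean_distance_matrix
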