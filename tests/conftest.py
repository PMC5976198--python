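"""Shared fixtures: small synthetic regions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from srisoscape.grids import Grid, GridSpec
from srisoscape.synthetic import SyntheticConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced synthetic region: 100x100 km, 15 units, 500 sites."""
    cfg = SyntheticConfig(nrows=100, ncols=100, n_units=15, n_sites=500, seed=7)
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_benchmark):
    return small_benchmark.matrix()


@pytest.fixture(scope="session")
def benchmark():
    """The standard benchmark: 200x200 km grid, 25 units, 1500 sites, seed 42."""
    return generate_benchmark(SyntheticConfig())


@pytest.fixture(scope="session")
def benchmark_matrix(benchmark):
    return benchmark.matrix()


@pytest.fixture
def toy_spec():
    return GridSpec("cea:0.0:45.0", 0.0, 4000.0, 1000.0, 4, 4)


@pytest.fixture
def toy_grid(toy_spec):
    vals = np.arange(16, dtype=float).reshape(4, 4)
    return Grid(toy_spec, vals, name="toy")


def make_samples(rows):
    """Helper: build a sample-records DataFrame from (site, lon, lat, sub, ratio)."""
    return pd.DataFrame(
        rows, columns=["site_id", "longitude", "latitude", "substrate", "ratio"]
    ).assign(source="test")
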