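import numpy as np
import pandas as pd
import pytest

from chubsdm import (LakescapeConfig, HabitatStack, generate_lakescape)


@pytest.fixture(scope="session")
def small_config():
    """Reduced synthetic world used across tests: same statistical
    defaults as the full study unit, smaller grid for speed."""
    return LakescapeConfig(grid_rows=100, grid_cols=150, n_aha=120,
                           n_tows=800, seed=11)


@pytest.fixture(scope="session")
def small_lakescape(small_config):
    return generate_lakescape(small_config)


@pytest.fixture(scope="session")
def default_lakescape():
    """Full-size stated world (200x300 grid, 2,066 tows), seed 1."""
    return LakescapeConfig(seed=1), *generate_lakescape(LakescapeConfig(seed=1))


@pytest.fixture
def tiny_stack():
    """4x5 two-variable stack with one nodata cell, 10 m cells."""
    depth = np.arange(20, dtype=float).reshape(4, 5) - 10.0
    fetch = np.linspace(100, 2000, 20).reshape(4, 5)
    depth[0, 0] = np.nan
    return HabitatStack(np.stack([depth, fetch]), ["depth", "fetch"],
                        cell_size_m=10.0, origin=(0.0, 40.0))


def make_samples(xs, ys, counts=None, areas=None):
    n = len(xs)
    return pd.DataFrame({
        "x": xs, "y": ys,
        "date": pd.Timestamp("2010-07-01"),
        "gear": "bottom_trawl",
        "area_swept_m2": areas if areas is not None else [1000.0] * n,
        "count": counts if counts is not None else [0] * n,
    })
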