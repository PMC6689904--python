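import numpy as np
import pandas as pd
import pytest

from gestnet import DyadMatrix, SyntheticConfig, load_fixture_attributes, simulate_dataset


@pytest.fixture(scope="session")
def fixture_attrs() -> pd.DataFrame:
    """The packaged 12-subject (6M/6F) attribute table."""
    return load_fixture_attributes()


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    cfg = SyntheticConfig(seed=42, n_follows_per_focal=8)
    attrs, scans, events, sociality = simulate_dataset(cfg)
    return cfg, attrs, scans, events, sociality


def random_dyad_matrix(n: int, rng: np.random.Generator, name: str = "m") -> DyadMatrix:
    vals = rng.normal(size=(n, n))
    np.fill_diagonal(vals, 0.0)
    labels = [f"n{i}" for i in range(n)]
    return DyadMatrix(labels, vals, name=name)
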