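import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import magcsr as m

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic bundle: 6 levels x 5 replicates, 60 genomes
    (15 C / 15 R / 15 S / 15 neutral), planted effects at their default
    strength, master seed 0."""
    return m.generate_dataset(m.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_genome_fit(default_bundle):
    """CSR strategy assignment of the default bundle's genomes."""
    b = default_bundle
    rel = b.abundance.div(b.abundance.sum(axis=1), axis=0)
    model = m.CSRModel(rel, b.sample_meta["regime"])
    return model.fit(n_sim=9999, alpha=0.05, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def euclidean_dm(values: np.ndarray, ids=None) -> m.DistanceMatrix:
    """1-D Euclidean distance matrix helper used by several tests."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    d = np.sqrt(((values[:, None, :] - values[None, :, :]) ** 2).sum(-1))
    if ids is None:
        ids = tuple(f"s{i}" for i in range(len(values)))
    return m.DistanceMatrix(tuple(ids), d)
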