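import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tagseq import SynthConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_counts(n_genes, n_samples, seed, low=0, high=400):
    """Small arbitrary count matrix (not from the generator)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.integers(low, high, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The human-cohort-scale fixture: 2,000 genes x 89 samples, 50 drivers."""
    return simulate_dataset(SynthConfig(seed=2024))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 300-gene x 40-sample dataset with 5 drivers."""
    return simulate_dataset(
        SynthConfig(n_genes=300, n_samples=40, n_tags=5, seed=7)
    )
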