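import warnings

import numpy as np
import pytest

from snitch import AnalysisConfig, classify_trajectories, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced benchmark design: 15 archetypes x 15 CpGs, 150 individuals."""
    return simulate_dataset(n_individuals=150, n_per_class=15, seed=7)


@pytest.fixture(scope="session")
def small_classification(small_dataset):
    cfg = AnalysisConfig(seed=7)
    return classify_trajectories(small_dataset.beta, small_dataset.sample_table, cfg)
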