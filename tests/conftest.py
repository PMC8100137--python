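import numpy as np
import pytest

from metabnn.tasks import SyntheticTaskSpec, generate_synthetic_tasks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tasks():
    """Three small permuted synthetic tasks for fast protocol tests."""
    spec = SyntheticTaskSpec(n_classes=4, n_features=24,
                             n_train_per_class=60, n_test_per_class=25, seed=7)
    return generate_synthetic_tasks(spec, 3)
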