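import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230511)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-class dataset shared by pipeline tests."""
    from loosewear import DatasetSpec, generate_dataset

    return generate_dataset(DatasetSpec(n_per_class=8, seed=42))
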