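import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_pool():
    """A small labeled synthetic sequence pool shared across tests."""
    from siliprot import SeqGenParams, gen_sequences

    records, labels = gen_sequences(SeqGenParams(n_ap=12, n_nap=15, seed=99))
    return records, labels
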