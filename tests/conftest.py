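import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet():
    """Suppress expected degenerate-pair warnings inside pipeline calls."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def three_type_nodes():
    """Summary nodes fabricated from three well-separated click types."""
    from echotype.simulate import THREE_TYPE_PRESET, synth_summary_nodes

    nodes, labels = synth_summary_nodes(THREE_TYPE_PRESET, n_per_type=40,
                                        sites=("S1", "S2"), rng_seed=11)
    return nodes, labels
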