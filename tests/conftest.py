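import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def toy():
    """Six-instance, two-class worked example (optimal cut at 2.65)."""
    from bayesdisc import toy_sample

    return toy_sample()


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
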