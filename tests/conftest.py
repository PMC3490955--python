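import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ladder4():
    """4-tip caterpillar: node ages 1, 2, 3."""
    from sympatree import Chronogram

    return Chronogram.from_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def balanced4():
    from sympatree import Chronogram

    return Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
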