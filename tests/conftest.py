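import numpy as np
import pytest
from hypothesis import settings

from mrhet.io import RegionLabel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def regions4():
    """Four tumor regions of one patient."""
    return [RegionLabel("PtX", f"T{i}") for i in range(1, 5)]


@pytest.fixture
def regions3():
    return [RegionLabel("PtX", f"T{i}") for i in range(1, 4)]


@pytest.fixture
def normal():
    return RegionLabel("PtX", "N", is_normal=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
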