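import numpy as np
import pytest

from schooldyn import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, fast school for structural tests."""
    return SimParams(n=20, z_l=2.0, z_a=10.0, sigma=0.01, total_time=10.0, seed=7)


@pytest.fixture
def eq1_params():
    """Parameters matching the per-term-normalized heading rule without
    self-alignment (the equal-attention reading of the update rule)."""
    return SimParams(term_weighting="normalized", align_self=False)
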