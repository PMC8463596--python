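import numpy as np
import pytest

from sonomil.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    return PhantomSpec()


@pytest.fixture
def small_table_rng():
    """Independent stream for random prediction tables."""
    return np.random.default_rng(987)
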