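import numpy as np
import pytest

from metallobsh.simulate import synthetic_family


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_family():
    """One shared synthetic family (reference + homologs + decoys)."""
    return synthetic_family(np.random.default_rng(777), length=650)
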