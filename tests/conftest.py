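import numpy as np
import pytest

from papunmix.phantom import PhantomConfig, bundled_stain_matrix, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bundled_A():
    return bundled_stain_matrix("papanicolaou_rgb")


@pytest.fixture(scope="session")
def small_phantom():
    """One 48x48 noiseless phantom shared across read-only tests."""
    return make_phantom(PhantomConfig(height=48, width=48, n_cells=4, seed=11))
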