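import numpy as np
import pytest

from patellamorph.synthetic import make_template


@pytest.fixture(scope="session")
def small_template():
    """Reduced-scheme template (6 anatomical + 20 curve + 40 surface) for speed."""
    return make_template(n_curve=20, n_surface=40)


@pytest.fixture(scope="session")
def full_template():
    """The standard 6 + 103 + 461 scheme."""
    return make_template()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_configuration(rng, k=10, scale=1.0):
    """Well-spread random landmark cloud (non-degenerate for TPS)."""
    return scale * rng.standard_normal((k, 3))
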