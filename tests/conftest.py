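import numpy as np
import pytest

from encounterdock import make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """The default synthetic two-chain complex with a planted charge patch."""
    return make_toy_complex(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng, max_angle=None):
    """Uniform-ish random proper rotation (optionally bounded rotation angle)."""
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    angle = rng.uniform(0, max_angle if max_angle is not None else np.pi)
    from encounterdock.landscape import rotation_exp
    return rotation_exp(angle * v)
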