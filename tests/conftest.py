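import numpy as np
import pytest
from hypothesis import settings

from alps_glymph.phantom import PhantomSpec, build_alps_phantom

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    """Compact noiseless phantom used across imaging tests."""
    return PhantomSpec(shape=(48, 48, 12))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_alps_phantom(small_spec)


def random_spd_tensor(rng, scale=1e-3):
    """Random symmetric positive-definite tensor with realistic magnitude."""
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    evals = rng.uniform(0.2, 2.5, size=3) * scale
    return Q @ np.diag(evals) @ Q.T
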