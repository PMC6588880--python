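import numpy as np
import pytest

from tmtriage import DEFAULT_CONFIG


@pytest.fixture
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
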