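import zlib

import numpy as np
import pytest


@pytest.fixture
def rng(request):
    """Per-test deterministic generator (independent of execution order)."""
    return np.random.default_rng(zlib.crc32(request.node.name.encode()))


def random_symmetric(p, rng, scale=1.0):
    a = rng.standard_normal((p, p)) * scale
    return (a + a.T) / 2.0


def random_correlation(p, rng):
    """A random well-conditioned correlation matrix."""
    a = rng.standard_normal((p, 2 * p))
    m = a @ a.T + 0.5 * p * np.eye(p)
    d = np.sqrt(np.diag(m))
    c = m / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c
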