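import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def orthogonal_centered_columns(n: int, k: int, scale: float = 1.0) -> np.ndarray:
    """k mutually orthogonal zero-sum columns of length n, squared norm n*scale.

    Built from a Helmert-style basis orthogonal to the all-ones vector, so
    column-centering leaves the matrix unchanged and C^T C = n * scale * I.
    """
    if k > n - 1:
        raise ValueError("need k <= n - 1 orthogonal zero-sum columns")
    basis = np.zeros((n, k))
    for j in range(1, k + 1):
        v = np.zeros(n)
        v[:j] = 1.0
        v[j] = -j
        basis[:, j - 1] = v / np.linalg.norm(v)
    return basis * np.sqrt(n * scale)
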