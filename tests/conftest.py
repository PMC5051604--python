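import numpy as np
import pytest

from drbench import DGPConfig, ObservedData, simulate_dataset


@pytest.fixture(scope="session")
def dgp1_small():
    """One draw of DGP 1 at n=1500, shared across read-only tests."""
    return simulate_dataset(DGPConfig(1, n=1500, seed=42))


@pytest.fixture(scope="session")
def dgp1_large():
    """A large DGP 1 draw for parametric-recovery checks."""
    return simulate_dataset(DGPConfig(1, n=100_000, seed=7))


def toy_data(n=40, seed=0, beta=(2.0, 3.0), effect=1.0, noise=0.0, p_treat=0.5):
    """Small linear-truth dataset: Y = b0 + b1*W6 + effect*A (+ noise)."""
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, 8))
    W[:, :5] = np.where(W[:, :5] > 0, 1.0, -1.0)
    A = (rng.random(n) < p_treat).astype(float)
    if A.min() == A.max():  # ensure both arms for tiny n
        A[0], A[1] = 0.0, 1.0
    Y = beta[0] + beta[1] * W[:, 5] + effect * A + noise * rng.standard_normal(n)
    return ObservedData(W=W, A=A, Y=Y)
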