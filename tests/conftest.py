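import logging

import numpy as np
import pytest

from osteoscreen import synthetic
from osteoscreen.datasets import Dataset

logging.getLogger("osteoscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def linear_dataset() -> Dataset:
    """Noiseless, synergy-free synthetic dataset (purely additive truth)."""
    return synthetic.generate_dataset(synthetic.linear_spec(120, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset() -> Dataset:
    """Default-design synthetic dataset with moderate noise."""
    return synthetic.generate_dataset(synthetic.default_spec(150, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def finite_difference_gradient(ws, X, Y, mask, h=1e-6):
    """Central-difference gradient over the packed trainable parameters."""
    from osteoscreen.networks import loss_and_gradient

    theta0 = ws.pack()
    fd = np.empty_like(theta0)
    for i in range(theta0.size):
        t = theta0.copy()
        t[i] += h
        ws.unpack(t)
        lp, _ = loss_and_gradient(ws, X, Y, mask)
        t[i] -= 2 * h
        ws.unpack(t)
        lm, _ = loss_and_gradient(ws, X, Y, mask)
        fd[i] = (lp - lm) / (2 * h)
    ws.unpack(theta0)
    return fd
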