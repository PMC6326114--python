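import numpy as np
import pytest

from diaglink import BinaryRecordDataset, HyperParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n, codes, p=0.3, prefix="P"):
    M = (rng.random((n, len(codes))) < p).astype(np.int8)
    return BinaryRecordDataset([f"{prefix}{i}" for i in range(n)], list(codes), M)


@pytest.fixture
def small_pair(rng):
    codes = [f"C{k}" for k in range(50)]
    A = random_dataset(rng, 20, codes, prefix="A")
    B = random_dataset(rng, 15, codes, prefix="B")
    return A, B


@pytest.fixture
def simple_hyper():
    return HyperParameters(
        pi_B=np.full(50, 0.3), eps_minus=0.01, eps_plus=0.01, pi_0=0.1
    )
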