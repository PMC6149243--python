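import numpy as np
import pytest

from molsample.fingerprints_io import FingerprintDataset
from molsample.synthetic_data import GeneratorSpec, generate


@pytest.fixture
def tiny_imbalanced() -> FingerprintDataset:
    """10 majority / 4 minority rows over 8 bits, fixed seed."""
    rng = np.random.default_rng(42)
    X = (rng.random((14, 8)) < 0.4).astype(np.uint8)
    y = np.array([0] * 10 + [1] * 4)
    return FingerprintDataset(ids=[f"c{i}" for i in range(14)], X=X, y=y)


@pytest.fixture
def medium_imbalanced() -> FingerprintDataset:
    """Generated 60 majority / 12 minority dataset over 64 bits."""
    ds, _ = generate(
        GeneratorSpec(n_bits=64, n_majority=60, n_minority=12, seed=7)
    )
    return ds


def random_imbalanced(seed: int, n_majority: int = 20, n_minority: int = 8,
                      n_bits: int = 16, density: float = 0.4) -> FingerprintDataset:
    rng = np.random.default_rng(seed)
    n = n_majority + n_minority
    X = (rng.random((n, n_bits)) < density).astype(np.uint8)
    y = np.array([0] * n_majority + [1] * n_minority)
    return FingerprintDataset(ids=[f"r{seed}-{i}" for i in range(n)], X=X, y=y)
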