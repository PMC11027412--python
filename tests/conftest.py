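import numpy as np
import pytest

from augur import LabeledDataset, PeptideRecord, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """Compact labeled synthetic dataset (40 pos / 80 neg)."""
    return generate_dataset(SyntheticSpec(n_pos=40, n_neg=80, seed=11))


@pytest.fixture(scope="session")
def separable_gaussians():
    """Two well-separated Gaussian clusters in 5-D: (X, y)."""
    rng = np.random.default_rng(3)
    pos = rng.normal(loc=3.0, scale=0.5, size=(100, 5))
    neg = rng.normal(loc=0.0, scale=0.5, size=(100, 5))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(100, dtype=int), np.zeros(100, dtype=int)])
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_dataset(sequences, label=None, prefix="p") -> LabeledDataset:
    return LabeledDataset(
        [
            PeptideRecord(f"{prefix}{i + 1}", s, label).validate()
            for i, s in enumerate(sequences)
        ]
    )
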