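import numpy as np
import pytest

from mdwhiten.synthetic_radar import (
    DatasetConfig, SignatureDataset, generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset() -> SignatureDataset:
    """A reduced synthetic population (6 subjects, 14 signatures/class)."""
    cfg = DatasetConfig(n_subjects=6, signatures_per_class=14)
    return SignatureDataset.from_signatures(generate_dataset(config=cfg, seed=11))


@pytest.fixture(scope="session")
def default_dataset() -> SignatureDataset:
    """The full study-condition population: 570 signatures, 33 subjects."""
    return SignatureDataset.from_signatures(generate_dataset(seed=20230828))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
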