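import numpy as np
import pandas as pd
import pytest

from orthosel import SyntheticConfig, counts_to_tpm, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic four-group dataset (counts, meta, lengths, truth)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_tpm(default_dataset):
    counts, _, lengths, _ = default_dataset
    return counts_to_tpm(counts, lengths)


@pytest.fixture
def tiny_counts():
    """2-gene x 4-sample count matrix with matching metadata and lengths."""
    counts = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 5, 5]],
        index=["G1", "G2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "tissue": ["A", "B", "A", "B"],
            "condition": ["tumor", "tumor", "normal", "normal"],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    lengths = pd.Series([1000, 2000], index=["G1", "G2"], name="length_bp")
    return counts, meta, lengths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
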