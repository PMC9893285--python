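import random

import pytest

from cdpep import PeptideDataset, PeptideRecord, default_dataset
from cdpep.sequences import AMINO_ACIDS


def make_dataset(sequences, label=None, prefix="s"):
    return PeptideDataset(
        [
            PeptideRecord(f"{prefix}{i + 1}", seq, label)
            for i, seq in enumerate(sequences)
        ]
    )


def random_peptide(rng: random.Random, min_len=9, max_len=20, alphabet=AMINO_ACIDS):
    L = rng.randint(min_len, max_len)
    return "".join(rng.choice(alphabet) for _ in range(L))


@pytest.fixture(scope="session")
def default_ds():
    """The default synthetic study dataset: 500+500, seed 42."""
    return default_dataset(seed=42)


@pytest.fixture(scope="session")
def small_ds():
    """A small synthetic dataset for fast unit tests."""
    return default_dataset(seed=7, n_positive=60, n_negative=60)
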