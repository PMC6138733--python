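import numpy as np
import pytest

from aapfuse.peptide_io import CANONICAL_ALPHABET, PeptideDataset, PeptideRecord


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_ALPHABET), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_dataset(rng):
    """20 labelled random peptides of length 10-20, 10 per class."""
    records = []
    for i in range(10):
        records.append(
            PeptideRecord(f"p{i}", random_peptide(rng, int(rng.integers(10, 21))), 1)
        )
        records.append(
            PeptideRecord(f"n{i}", random_peptide(rng, int(rng.integers(10, 21))), 0)
        )
    return PeptideDataset(records)
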