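import numpy as np
import pytest

from promoterbench.negatives import BaseFrequencies
from promoterbench.seqio import SequenceRecord, SequenceSet


def random_window(rng: np.random.Generator, length: int = 81) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_set(rng) -> SequenceSet:
    """Ten random 81-nt windows, unlabeled."""
    records = [
        SequenceRecord(f"s{i}", random_window(rng)) for i in range(10)
    ]
    return SequenceSet(name="small", records=records)


@pytest.fixture
def ecoli_freqs() -> BaseFrequencies:
    return BaseFrequencies.ecoli_like()


def make_set(seqs, name="set", label=None, source="experimental"):
    records = [
        SequenceRecord(f"{name}_{i}", s, label=label, source=source)
        for i, s in enumerate(seqs)
    ]
    return SequenceSet(name=name, records=records, window_length=len(seqs[0]))
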