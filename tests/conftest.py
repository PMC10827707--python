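import numpy as np
import pytest

from gruclust.preprocess import Vocabulary
from gruclust.seqdata import SyntheticConfig, generate_synthetic

#: The canonical 16-entry 2-mer vocabulary used by the worked tokenization
#: example ("CCTCCCGAGAGA" -> 2, 4, 8, 2, 2, 14, 9, 6, 9, 6, 9).
PRINTED_2MER_VOCAB = {
    "gg": 1, "cc": 2, "gc": 3, "ct": 4, "tg": 5, "ag": 6, "ca": 7, "tc": 8,
    "ga": 9, "tt": 10, "aa": 11, "gt": 12, "ac": 13, "cg": 14, "at": 15, "ta": 16,
}


@pytest.fixture
def dimer_vocab() -> Vocabulary:
    return Vocabulary.from_mapping(PRINTED_2MER_VOCAB)


@pytest.fixture(scope="session")
def small_labelled_records():
    """600 short separable sequences for fast model-level tests."""
    return generate_synthetic(SyntheticConfig(n_per_class=300, seq_length=60, seed=7))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
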