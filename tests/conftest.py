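import itertools

import numpy as np
import pytest

from indelfold.folding import ToyEngine
from indelfold.sitefinder import AffinityTable, KMER_LEN

BASES = "ACGU"


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def sparse_table(nonzero: dict) -> AffinityTable:
    """Affinity table that is zero everywhere except the given 7-mers."""
    scores = {
        "".join(p): 0.0 for p in itertools.product(BASES, repeat=KMER_LEN)
    }
    scores.update(nonzero)
    return AffinityTable(scores)


@pytest.fixture(scope="session")
def toy_engine():
    return ToyEngine()
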