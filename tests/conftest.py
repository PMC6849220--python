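import numpy as np
import pytest

from allomum.genome_io import Genome, SequenceRecord


def random_genome(name: str, length: int, gc: float = 0.5, seed: int = 0,
                  n_records: int = 1) -> Genome:
    """Uniform-composition random genome for tests."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    step = length // n_records
    recs = [SequenceRecord(f"s{i + 1}",
                           seq[i * step: (i + 1) * step if i < n_records - 1 else length])
            for i in range(n_records)]
    return Genome(name, recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
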