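import numpy as np
import pytest

from hrrscan.intervals import Genome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """A seeded 2 x 100 kb genome with sequence."""
    rng = np.random.default_rng(20240917)
    bases = np.array(list("ACGT"))
    seqs = {
        c: "".join(bases[rng.integers(0, 4, size=100_000)]) for c in ("chr1", "chr2")
    }
    return Genome({c: 100_000 for c in seqs}, seqs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
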