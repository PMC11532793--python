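import numpy as np
import pytest

from dividedcounts import ECCounts, ECStructure, TranscriptCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_tx_catalog():
    return TranscriptCatalog(
        transcript_id=("t1", "t2"),
        effective_length=np.array([1000.0, 1000.0]),
        gene_id=("g1", "g1"),
    )


@pytest.fixture
def three_tx_catalog():
    return TranscriptCatalog(
        transcript_id=("t1", "t2", "t3"),
        effective_length=np.array([800.0, 1200.0, 1500.0]),
        gene_id=("g1", "g1", "g1"),
    )


def random_three_tx_instance(rng, max_reads=200):
    """A random 3-transcript EC instance with overlapping classes."""
    structure = ECStructure(((0,), (1,), (2,), (0, 1), (1, 2), (0, 1, 2)))
    counts = rng.multinomial(
        int(rng.integers(20, max_reads + 1)),
        rng.dirichlet(np.ones(len(structure))),
    )
    return structure, ECCounts(counts)
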