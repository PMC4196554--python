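import numpy as np
import pytest

from oligopipe.seq_io import AlignedReadSet, read_tree


def make_readset(sequences, groups=None, samples=None, taxon="toy"):
    """AlignedReadSet from bare sequence strings with auto ids."""
    n = len(sequences)
    groups = groups or ["g1"] * n
    samples = samples or [f"s{i}" for i in range(n)]
    reads = [(f"r{i}", s) for i, s in enumerate(sequences)]
    return AlignedReadSet.from_sequences(reads, samples, groups, taxon)


def column_readset(column, **kw):
    """Single-column readset: one read per character."""
    return make_readset([c for c in column], **kw)


@pytest.fixture
def toy_tree():
    return read_tree("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def quartet_tree():
    return read_tree("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
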