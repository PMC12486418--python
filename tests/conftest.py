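import numpy as np
import pytest

from halocline.tables import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(counts, taxa=None, samples=None) -> CountTable:
    counts = np.asarray(counts)
    taxa = taxa or [f"OTU{i + 1}" for i in range(counts.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(counts.shape[1])]
    return CountTable(taxa, samples, counts)


def random_table(rng, n_taxa=20, n_samples=8, lam=5.0) -> CountTable:
    counts = rng.poisson(lam, size=(n_taxa, n_samples))
    # make every sample non-empty
    counts[0] += 1
    return make_table(counts)


@pytest.fixture
def small_table():
    return make_table([[5, 0, 2], [3, 7, 1], [2, 3, 7]])
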