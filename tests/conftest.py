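import numpy as np
import pytest

from comparthic.hic_io import RAW, ContactMatrix, GenomeBins
from comparthic.synthetic import block_profile, simulate_contact_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bins():
    return GenomeBins(chrom="chrS", resolution=40_000, n_bins=6)


def make_matrix(counts, resolution=40_000, chrom="chrS"):
    counts = np.asarray(counts, dtype=float)
    bins = GenomeBins(chrom=chrom, resolution=resolution, n_bins=counts.shape[0])
    return ContactMatrix(bins=bins, counts=counts, state=RAW)


@pytest.fixture
def plaid_cm(rng):
    """Medium two-condition-free plaid matrix with planted profile and biases."""
    c = block_profile(120, block_size=15)
    cm, bias = simulate_contact_map(c, rng, depth=4e5)
    return cm, c, bias
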