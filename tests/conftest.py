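import numpy as np
import pandas as pd
import pytest

from stratqtl.io_formats import GenotypeDataset, SampleRecord, VariantRecord


def make_dataset(calls, statuses, alleles=None, chrom="1"):
    """Build a small GenotypeDataset from a calls matrix and status list."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    assert len(statuses) == n_samples
    if alleles is None:
        alleles = [("A", "G")] * n_variants
    samples = [
        SampleRecord(f"F{i + 1}", f"I{i + 1}", status)
        for i, status in enumerate(statuses)
    ]
    variants = [
        VariantRecord(chrom, f"rs{j + 1}", 100 * (j + 1), a, b)
        for j, (a, b) in enumerate(alleles)
    ]
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def blob_matrix():
    """Two well-separated archetype blobs (pairwise mean L2 >= 10), noise 0.3."""
    rng = np.random.default_rng(7)
    n_items = 30
    arch = np.zeros((2, n_items))
    arch[0] = 2.5
    arch[1] = 0.5  # L2 distance = 2.0 * sqrt(30) ~ 11
    labels = np.repeat([0, 1], [40, 35])
    x = arch[labels] + rng.normal(0, 0.3, size=(75, n_items))
    matrix = pd.DataFrame(
        x,
        index=[f"case{i}" for i in range(75)],
        columns=[f"item{j}" for j in range(n_items)],
    )
    return matrix, labels
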