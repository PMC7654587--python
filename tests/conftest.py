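import numpy as np
import pandas as pd
import pytest

from radialct.hic_io import BinTable, ChromProperties, HicMatrix
from radialct.synthetic import CHROMS, HG19_LENGTHS, SyntheticSpec, make_dataset


def small_genome(divisor: int = 40):
    """hg19-proportioned genome shrunk for fast unit tests (~300 bins at 40)."""
    return [(c, HG19_LENGTHS[c] // divisor) for c in CHROMS]


def small_spec(**kw):
    """Tiny-genome spec for plumbing tests.

    The steeper cis decay (alpha 1.7) keeps the far-cis contact floor in
    the same range as strong trans contacts, as happens at the default
    scale through the longer chromosomes; without it no trans contact
    clears the 95th-percentile threshold on a ~300-bin map.
    """
    kw.setdefault("genome", small_genome())
    kw.setdefault("cis_alpha", 1.7)
    return SyntheticSpec(**kw)


@pytest.fixture(scope="session")
def gene_density_dataset():
    """Default small-genome map with planted gene-density organization."""
    return make_dataset(SyntheticSpec(organization="gene_density", seed=1))


@pytest.fixture(scope="session")
def tiny_dataset():
    """~300-bin map for tests where layout/scan cost matters."""
    return make_dataset(small_spec(organization="gene_density", seed=3))


@pytest.fixture
def three_chrom_bins():
    rows = []
    for chrom, nbins in [("chrA", 4), ("chrB", 3), ("chrC", 3)]:
        for i in range(nbins):
            rows.append((chrom, i * 100, (i + 1) * 100))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return BinTable(df)


@pytest.fixture
def three_chrom_matrix(three_chrom_bins):
    rng = np.random.default_rng(7)
    m = len(three_chrom_bins)
    vals = rng.integers(0, 20, size=(m, m)).astype(float)
    vals = np.triu(vals) + np.triu(vals, 1).T
    return HicMatrix(vals, three_chrom_bins)


@pytest.fixture
def props23():
    """Property table covering the canonical 23 chromosomes."""
    from radialct.synthetic import hg19_properties

    return hg19_properties()
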