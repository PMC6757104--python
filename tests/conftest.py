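import numpy as np
import pytest

from gwasmix.genotype_io import GenotypeMatrix, SuffStats


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gm():
    """2 SNPs x 3 subjects (2 cases, 1 control) with one missing genotype."""
    return GenotypeMatrix(
        snp_ids=["rs1", "rs2"],
        dosages=np.array([[0, 1, 2], [1, -1, 0]], dtype=np.int8),
        phenotype=np.array([1, 1, 0], dtype=np.int8),
        subject_ids=["s1", "s2", "s3"],
    )


def random_suffstats(rng, n_snps=20, n_x=25, n_y=25):
    """Valid random sufficient statistics via actual multinomial genotypes."""
    theta = rng.uniform(0.05, 0.5, size=(n_snps, 2))
    dx = rng.binomial(2, theta[:, :1], size=(n_snps, n_x))
    dy = rng.binomial(2, theta[:, 1:], size=(n_snps, n_y))
    return SuffStats(
        snp_ids=np.array([f"s{i}" for i in range(n_snps)], dtype=object),
        n_x=np.full(n_snps, n_x),
        m_x=dx.sum(1),
        h_x=(dx == 1).sum(1),
        n_y=np.full(n_snps, n_y),
        m_y=dy.sum(1),
        h_y=(dy == 1).sum(1),
    )
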