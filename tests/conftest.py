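import numpy as np
import pytest

from campina import GenotypeMatrix, PopulationMap, SiteRecord


def make_site(chrom, pos, genotypes, gq=None, annotation=None):
    return SiteRecord(
        chrom=chrom,
        pos=pos,
        ref_allele="A",
        alt_allele="T",
        genotypes=np.asarray(genotypes, dtype=np.int16),
        genotype_quality=None if gq is None else np.asarray(gq, dtype=float),
        annotation=annotation,
    )


@pytest.fixture
def toy_matrix():
    """Six samples (two populations of three), five sites on one chromosome."""
    sites = [
        make_site("chr1", 100, [0, 1, 2, 0, 0, 1]),
        make_site("chr1", 250, [2, 2, 2, 0, 0, 0]),
        make_site("chr1", 900, [1, 1, 0, 1, 2, 2]),
        make_site("chr1", 1500, [0, 0, 0, 0, 0, 1]),
        make_site("chr1", 2100, [2, 1, 2, 2, 2, 2]),
    ]
    return GenotypeMatrix(
        samples=["a1", "a2", "a3", "b1", "b2", "b3"], sites=sites
    )


@pytest.fixture
def toy_popmap():
    return PopulationMap(
        assignment={"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
        coordinates={
            "a1": (-2.0, -57.0),
            "a2": (-2.0, -57.0),
            "a3": (-2.1, -57.1),
            "b1": (-20.0, -40.5),
            "b2": (-20.0, -40.5),
            "b3": (-19.9, -40.4),
        },
    )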