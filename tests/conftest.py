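import numpy as np
import pytest

from tetermi.formats_io import GeneModel, GenomicInterval, TEAnnotation
from tetermi.synthetic_data import SimConfig, generate_gene_set, generate_pet_library


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genes=20, n_celltypes=3, genome_length=600_000, library_size=50_000, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genes, tes, truth = generate_gene_set(small_config)
    libs = {
        ct: generate_pet_library(genes, truth, ct, small_config)
        for ct in small_config.celltype_names
    }
    return genes, tes, truth, libs


@pytest.fixture
def plus_gene() -> GeneModel:
    """A 10 kb plus-strand gene with 3 exons and a CDS from 2,150 to 9,300."""
    return GeneModel(
        id="gplus",
        locus=GenomicInterval("chr1", 2000, 12000, "+"),
        exon_blocks=((2000, 2300), (5000, 5600), (9000, 12000)),
        cds=(2150, 9300),
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel(
        id="gminus",
        locus=GenomicInterval("chr1", 20000, 30000, "-"),
        exon_blocks=((20000, 23000), (25000, 25600), (29700, 30000)),
        cds=(22700, 29850),
    )


@pytest.fixture
def alu_te() -> TEAnnotation:
    return TEAnnotation(
        id="teA",
        span=GenomicInterval("chr1", 1000, 1300, "+"),
        family="Alu",
        subfamily="AluY",
        consensus_begin=1,
        consensus_end=300,
        consensus_length=311,
    )
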