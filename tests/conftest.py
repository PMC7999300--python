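import numpy as np
import pytest

from clonoscope.genome import GenomeConfig, GenomeModel, GeneModel, build_genome


@pytest.fixture(scope="session")
def genome_default():
    """Default fixture genome: 3 × 2 Mb, 60 genes, CpG-depleted."""
    return build_genome(GenomeConfig(), seed=1)


@pytest.fixture(scope="session")
def genome_small():
    """Small, fast genome for sampling-heavy tests."""
    config = GenomeConfig(
        chrom_sizes={"chr1": 300_000, "chr2": 300_000},
        n_genes=12,
        gene_span_range_bp=(3_000, 40_000),
        timing_domain_bp=50_000,
    )
    return build_genome(config, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_single_exon_genome(seq: str, strand: str = "+") -> GenomeModel:
    """One chromosome, one gene whose single exon spans the whole sequence."""
    gene = GeneModel(
        gene_id="g1", chrom="chr1", strand=strand, exons=((0, len(seq)),)
    )
    return GenomeModel(
        chromosomes={"chr1": seq},
        genes=[gene],
        timing_domains=[("chr1", 0, len(seq), "early")],
    )
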