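import numpy as np
import pytest

from uvfrac import SimConfig, simulate_experiment
from uvfrac.simdata import GeneModel


def make_gene(
    span: int = 1000,
    gene_id: str = "g1",
    biotype: str = "mRNA",
    strand: str = "+",
    tx_start: int = 101,
    exons=None,
    cds_length: int = 0,
) -> GeneModel:
    """Single-exon gene helper; pass explicit exons for multi-exon models."""
    tx_end = tx_start + span - 1
    if exons is None:
        exons = ((tx_start, tx_end),)
    return GeneModel(
        gene_id=gene_id,
        biotype=biotype,
        chrom="chr1",
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=tuple(exons),
        cds_length=cds_length,
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genes={"mRNA": 200, "annotated_lncRNA": 50, "novel_lncRNA": 50, "TUCP": 20},
        library_size=200_000,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """(models, truths, counts, lengths, design) for a 320-gene experiment."""
    return simulate_experiment(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
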