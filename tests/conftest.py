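import numpy as np
import pytest

from wnttargets.io_formats import GeneModel, GenomeIndex, Peak


def make_gene(
    symbol="G1",
    chrom="chr1",
    strand="+",
    tx_start=10000,
    tx_end=15000,
    cds=None,
    exons=None,
):
    """Compact GeneModel builder for hand-crafted annotation layouts."""
    if exons is None:
        exons = [(tx_start, tx_start + 500), (tx_end - 500, tx_end)]
    if cds is None:
        cds = (tx_start + 100, tx_end - 100)
    return GeneModel(
        symbol=symbol,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds[0],
        cds_end=cds[1],
        exon_starts=tuple(s for s, _ in exons),
        exon_ends=tuple(e for _, e in exons),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_genome():
    """Two featureless chromosomes for shuffle/placement tests."""
    return GenomeIndex({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default conditions, shared
    read-only across tests."""
    from wnttargets.synthetic_data import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=2024))
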