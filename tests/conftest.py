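import numpy as np
import pandas as pd
import pytest

from estro.regions import GenomicRegion, Loop
from estro.simulate import SimulationConfig, assign_ground_truth, generate_annotation


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=300, n_cells_per_timepoint=150)


@pytest.fixture(scope="session")
def small_genes(small_config):
    return generate_annotation(small_config.n_genes, seed=101)


@pytest.fixture(scope="session")
def small_truth(small_genes, small_config):
    return assign_ground_truth(small_genes, small_config, seed=102)


def make_region(chrom="chr1", start=0, end=100, id=None):
    return GenomicRegion(chrom, start, end, id)


def make_loop(a_start, a_end, b_start, b_end, reads=10, fdr=0.01, chrom="chr1"):
    return Loop(
        GenomicRegion(chrom, a_start, a_end),
        GenomicRegion(chrom, b_start, b_end),
        reads=reads,
        fdr=fdr,
    )


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["chr1", "chr1", "chr1"],
            "tss": [10_000, 60_000, 120_000],
            "strand": ["+", "-", "+"],
            "length": [5_000, 20_000, 8_000],
        }
    )
    return genes.set_index("gene_id", drop=False)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
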