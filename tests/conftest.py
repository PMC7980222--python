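import numpy as np
import pandas as pd
import pytest

from methylbind import SimulationConfig, make_genome, simulate_wgbs


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study config: tiny genome, short genes, light libraries."""
    return SimulationConfig(
        seed=5,
        genome_length=60_000,
        n_chromosomes=2,
        coverage_mean=8.0,
        n_genes=40,
        gene_length_mu=float(np.log(400.0)),
        gene_length_sigma=0.4,
        library_size=30_000,
        n_replicates=2,
        bound_contexts=("CG",),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def small_records(small_genome, small_config):
    return simulate_wgbs(small_genome, small_config)


def make_records(rows):
    """Build a methylation record frame from (chrom, pos, strand, context,
    meth, total) tuples."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context", "meth_count", "total_count"],
    )
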