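import pytest

from ambercode import load_code_table
from ambercode.synthdata import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def table11():
    return load_code_table(11)


@pytest.fixture(scope="session")
def table15():
    return load_code_table(15)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic genome for unit-level tests (fast to predict on)."""
    cfg = SimConfig(
        seed=7,
        contig_len=24_000,
        n_genes_code15=8,
        n_genes_code11=8,
        gene_len_codons=(120, 220),
        tag_per_gene=6.0,
    )
    contig, truth = simulate_genome(cfg)
    return cfg, contig, truth
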