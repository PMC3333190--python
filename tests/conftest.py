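import numpy as np
import pandas as pd
import pytest

from captss.synthetic_data import SimConfig, simulate_genome, simulate_reads


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    rng = np.random.default_rng(101)
    return {"c1": "".join(rng.choice(list("ACGT"), 200_000))}


@pytest.fixture(scope="session")
def small_sim():
    """A small ascidian-mode simulation shared by pipeline-level tests."""
    cfg = SimConfig.ascidian(seed=42, genome_length=2_000_000, n_genes=100, n_reads=50_000)
    sim = simulate_genome(cfg)
    datasets, truth = simulate_reads(sim)
    return sim, datasets, truth


def position_table(rows):
    """Build a TSS position table from (contig, strand, pos, ppm) tuples."""
    df = pd.DataFrame(rows, columns=["contig", "strand", "pos", "ppm"])
    df["count_d1"] = 1
    df["count"] = 1
    return df[["contig", "strand", "pos", "count_d1", "count", "ppm"]]
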