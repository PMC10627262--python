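import numpy as np
import pandas as pd
import pytest

from promstab import scan as sc
from promstab import stability as stab
from promstab.promoters import extract_promoters
from promstab.synth import GenomeSpec, plant, simulate_genome


@pytest.fixture(scope="session")
def pwms():
    return sc.default_pwms()


@pytest.fixture(scope="session")
def octamers():
    return sc.default_octamers()


@pytest.fixture(scope="session")
def planted_genome(tmp_path_factory):
    """A 50-gene genome on both strands with one planted element per gene
    for the first 40 genes (cycling TATA, YPatch, Inr, CA, GA); the last
    10 genes carry no element."""
    elements = ["TATA", "YPatch", "Inr", "CA", "GA"]
    element_plan = {i: [plant(elements[i % 5])] for i in range(40)}
    spec = GenomeSpec(n_genes=50, strand_fraction=0.5, element_plan=element_plan, seed=11)
    genome = simulate_genome(spec)
    outdir = tmp_path_factory.mktemp("planted_genome")
    paths = genome.write(outdir)
    return genome, paths


@pytest.fixture(scope="session")
def planted_promoters(planted_genome):
    genome, paths = planted_genome
    promoters = extract_promoters(paths["fasta"], paths["gff3"])
    return {p.transcript_id: p for p in promoters}


def random_count_matrix(n_genes=30, n_samples=6, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.poisson(50, size=(n_genes, n_samples)) + 1
    return pd.DataFrame(
        x,
        index=[f"t{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture
def counts_matrix():
    return random_count_matrix()


@pytest.fixture(scope="session")
def stability_tiny():
    """Stability table for a tiny deterministic matrix used across tests."""
    rng = np.random.default_rng(42)
    x = rng.poisson(40, size=(40, 10)) + 1
    df = pd.DataFrame(
        x,
        index=[f"t{i:03d}" for i in range(40)],
        columns=[f"s{j}" for j in range(10)],
    )
    return stab.stability_table(df)
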