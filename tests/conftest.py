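import numpy as np
import pytest

from caldera.hic_io import ContactMatrix
from caldera.pipeline import RunConfig, run_chromosome
from caldera.simulate import (SyntheticSpec, simulate_contact_map,
                              simulate_genes)


def sym_random(n, rng, scale=10):
    m = rng.poisson(scale, size=(n, n)).astype(float)
    return (m + np.triu(m, 1).T - np.tril(m, -1))


@pytest.fixture
def small_cm():
    rng = np.random.default_rng(0)
    m = rng.poisson(8, size=(30, 30)).astype(float)
    m = np.triu(m) + np.triu(m, 1).T
    return ContactMatrix("chr1", 40_000, m)


@pytest.fixture(scope="session")
def planted_map():
    """Default synthetic study conditions, seed 1 (plaid map, no nested)."""
    spec = SyntheticSpec(seed=1)
    cm, gt = simulate_contact_map(spec)
    return spec, cm, gt


@pytest.fixture(scope="session")
def planted_gene_density(planted_map):
    spec, cm, gt = planted_map
    genes = simulate_genes(gt, spec.bin_size, seed=1)
    gd = np.zeros(cm.retained.size)
    np.add.at(gd, (genes["start"].to_numpy() // spec.bin_size), 1)
    return gd


@pytest.fixture(scope="session")
def planted_result(planted_map, planted_gene_density):
    """Full pipeline result on the planted seed-1 map (shared; expensive)."""
    spec, cm, gt = planted_map
    return run_chromosome(cm, planted_gene_density, RunConfig(seed=1))
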