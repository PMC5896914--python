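import numpy as np
import pytest

from msatnet import (
    GenotypeTable,
    SimulationConfig,
    planted_communities_preset,
    simulate_hierarchical,
    study_preset,
)


def make_table(genotypes, locus_names=None):
    """Build a GenotypeTable from {site: [((a1, a2), ...), ...]} nested as
    site -> individuals -> per-locus pairs."""
    individual_ids, site_ids, calls = [], [], []
    i = 0
    for site, inds in genotypes.items():
        for pairs in inds:
            individual_ids.append(f"{site}_{i}")
            site_ids.append(site)
            calls.append(list(pairs))
            i += 1
    n_loci = len(calls[0])
    if locus_names is None:
        locus_names = [f"L{k + 1}" for k in range(n_loci)]
    return GenotypeTable(individual_ids, site_ids, locus_names, np.asarray(calls))


@pytest.fixture
def two_site_table():
    """Two sites, one locus: site A = {(1,1), (1,2)}, site B = {(2,2), (2,3)}."""
    return make_table(
        {
            "A": [((1, 1),), ((1, 2),)],
            "B": [((2, 2),), ((2, 3),)],
        }
    )


@pytest.fixture(scope="session")
def study_table():
    """One study-preset simulation, shared across read-only tests."""
    table, truth = simulate_hierarchical(study_preset(seed=42))
    return table, truth


@pytest.fixture(scope="session")
def planted_table():
    table, truth = simulate_hierarchical(planted_communities_preset(seed=42))
    return table, truth


@pytest.fixture
def panmictic_config():
    def factory(seed):
        return SimulationConfig(F_community=1e-6, F_site=1e-6, seed=seed)

    return factory
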