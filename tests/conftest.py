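import numpy as np
import pandas as pd
import pytest

from micronet import AbundanceTable, EcosystemSpec, TaxonomyMap, generate_asv_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table():
    """5 ASVs x 6 samples with a mix of common, rare and sparse ASVs."""
    counts = pd.DataFrame(
        {
            "s1": [500, 300, 150, 40, 10],
            "s2": [450, 350, 120, 60, 0],
            "s3": [480, 280, 170, 50, 0],
            "s4": [520, 310, 140, 20, 0],
            "s5": [470, 330, 160, 10, 0],
            "s6": [510, 290, 130, 30, 1],
        },
        index=["asv1", "asv2", "asv3", "asv4", "asv5"],
    )
    domain = pd.Series(
        ["bacteria", "bacteria", "bacteria", "fungi", "fungi"], index=counts.index
    )
    eco = pd.Series("meadow", index=counts.columns)
    return AbundanceTable(counts, domain=domain, ecosystem=eco)


@pytest.fixture
def planted_table():
    """Planted 4-module community at the standard benchmark conditions."""
    spec = EcosystemSpec(
        name="bench", n_samples=30, n_bacterial_asvs=45, n_fungal_asvs=15,
        n_modules=4, module_rho=0.85, depth=50_000, seed=11,
    )
    return generate_asv_table(spec)


@pytest.fixture
def taxonomy():
    lineages = pd.DataFrame(
        {
            "kingdom": ["Bacteria", "Bacteria", "Bacteria", "Fungi", "Fungi"],
            "phylum": ["Proteobacteria", "Proteobacteria", "Actinobacteria",
                       "Ascomycota", "Basidiomycota"],
        },
        index=["asv1", "asv2", "asv3", "asv4", "asv5"],
    )
    return TaxonomyMap(lineages)
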