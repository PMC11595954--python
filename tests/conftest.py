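import pytest

from mitomarker.synthetic_data import SimConfig, example_genus_collection, simulate_collection


@pytest.fixture(scope="session")
def example_collection():
    """Nine-taxon, three-clade collection with planted marker diagnostics."""
    return example_genus_collection(seed=1)


@pytest.fixture(scope="session")
def small_collection():
    """Five random taxa, substitution-only core genes, no rRNA introns."""
    config = SimConfig(
        n_taxa=5,
        genome_length=35_000,
        rrna_intron_count_range=(0, 0),
        seed=11,
    )
    return simulate_collection(config)
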