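import pytest

from ruleout16s import (
    ReferenceDatabase,
    SimulationConfig,
    TypeStrainRecord,
    simulate_database,
    simulate_reads,
)


@pytest.fixture
def tiny_db():
    """Two hand-written strains of different species."""
    return ReferenceDatabase(
        [
            TypeStrainRecord("X1", "Genus speciesa", "ACGTACGTACGTACGTACGT"),
            TypeStrainRecord("X2", "Genus speciesb", "TTTTACGTACGTACGTAAAA"),
        ]
    )


@pytest.fixture(scope="session")
def sim_config():
    """Small, fast simulation: 3 species, short genes."""
    return SimulationConfig(
        n_species=3,
        gene_length=400,
        between_species_divergence=0.15,
        region_start=20,
        region_end=120,
        inside_rate=0.0,
        n_reads=9,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_db(sim_config):
    return simulate_database(sim_config)


@pytest.fixture(scope="session")
def sim_reads(sim_db, sim_config):
    return simulate_reads(sim_db, sim_config)
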