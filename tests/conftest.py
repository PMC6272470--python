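import pytest

from lectinscape.records import FamilyAssignment
from lectinscape.synthetic_genome import SimulationConfig, simulate


def make_assignment(gene_id: str, family: str) -> FamilyAssignment:
    return FamilyAssignment(
        gene_id=gene_id, families=(family,), primary_family=family
    )


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated genome shared by read-only tests."""
    config = SimulationConfig(
        seed=11,
        n_chromosomes=5,
        genes_per_chromosome=250,
        n_tandem_arrays=10,
        n_collinear_blocks=20,
        n_scattered_lectins=40,
    )
    return config, simulate(config)


@pytest.fixture(scope="session")
def defs():
    from lectinscape.family_classifier import default_family_definitions

    return default_family_definitions()
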