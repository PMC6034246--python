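import pytest

from mitoburden import default_gene_map
from mitoburden.synthetic import SimulationConfig, generate_cohort, reference_genome


@pytest.fixture(scope="session")
def gene_map():
    return default_gene_map()


@pytest.fixture(scope="session")
def reference():
    return reference_genome()


@pytest.fixture(scope="session")
def default_cohort():
    """One study-shaped synthetic cohort shared across tests (seed 1)."""
    dataset, truth = generate_cohort(SimulationConfig(seed=1))
    return dataset, truth
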