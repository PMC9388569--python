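import pytest

from gliomics.genome import build_toy_genome
from gliomics.simulate import SimulationConfig, simulate_paired_cohort, simulate_tcga_like_tables


@pytest.fixture(scope="session")
def genome():
    return build_toy_genome()


@pytest.fixture(scope="session")
def bundle():
    """Default paired cohort: 5 patients, case2 a POLE hypermutator."""
    return simulate_paired_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def cohort():
    """Reference cohort of 200 cases with planted survival and methylation structure."""
    return simulate_tcga_like_tables(SimulationConfig(seed=7, n_cohort=200))
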