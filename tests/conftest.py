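import pytest

from puritylens import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-model cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11, n_tumour=60, n_normal=30, n_genes=300))
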