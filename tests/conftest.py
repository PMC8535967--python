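import numpy as np
import pytest

from suppscan.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One suppression-structured cohort at the study sample size."""
    return simulate_cohort(SimulationConfig(seed=7, n_null_snps=40))


@pytest.fixture(scope="session")
def clean_cohort():
    """Same structure but no genotype missingness (for exact identities)."""
    return simulate_cohort(SimulationConfig(seed=11, n_null_snps=10,
                                            missing_rate_genotype=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
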