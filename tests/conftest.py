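import numpy as np
import pytest

from lfqpanel import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """15 samples x 40 proteins, 3 planted markers, 10% missingness."""
    config = SimulationConfig(
        n_group_c=8, n_group_a=7, n_proteins=40, n_planted=3,
        effect_size=2.5, missing_rate=0.1, seed=3,
    )
    matrix, clinical, truth = simulate_cohort(config)
    return config, matrix, clinical, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    """Complete-case cohort for ground-truth panel recovery: 20+20 samples,
    30 proteins, 3 planted at d=2.5, no missingness."""
    config = SimulationConfig(
        n_group_c=20, n_group_a=20, n_proteins=30, n_planted=3,
        effect_size=2.5, missing_rate=0.0, seed=7,
    )
    matrix, clinical, truth = simulate_cohort(config)
    return config, matrix, clinical, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
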