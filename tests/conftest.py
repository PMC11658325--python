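import numpy as np
import pytest

from wingid.simulate import (
    MorphoSimParams,
    simulate_coi_dataset,
    simulate_morpho_dataset,
    study_morpho_params,
    study_seq_params,
)


@pytest.fixture(scope="session")
def small_morpho():
    """Three well-separated species, 20 specimens each, no replicates."""
    params = MorphoSimParams(
        n_species=3,
        n_per_species=[20, 20, 20],
        cs_mean=[2.2, 2.8, 3.5],
        cs_sd=[0.1, 0.1, 0.1],
        offset_magnitudes=[0.04, 0.04, 0.04],
        within_sd=0.01,
        digitizing_sd=0.0,
        allometric_slope=0.0,
        seed=11,
    )
    return simulate_morpho_dataset(params)


@pytest.fixture(scope="session")
def study_morpho():
    """Full seven-species study design (253 specimens)."""
    return simulate_morpho_dataset(study_morpho_params(seed=7))


@pytest.fixture(scope="session")
def study_coi():
    """Seven species x 10 COI-like 658-bp sequences."""
    return simulate_coi_dataset(study_seq_params(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
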