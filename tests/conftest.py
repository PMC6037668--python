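import numpy as np
import pytest

from microscan.synthetic import PlantedEffect, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small twin cohort with planted effects, shared across tests."""
    return SimConfig(
        n_individuals=600,
        n_twin_pairs=150,
        phenotype_specs=[
            ("disease_a", 0.20),
            ("disease_b", 0.10),
            ("disease_c", 0.15),
            ("disease_d", 0.05),
            ("med_x", 0.15),
            ("med_y", 0.10),
        ],
        phi_targets=[("disease_a", "med_x", 0.45)],
        n_trait_blocks=5,
        traits_per_block=3,
        within_block_rho=0.7,
        planted_effects=[
            PlantedEffect("disease_a", "block01_t1", 0.8),
            PlantedEffect("med_x", "block01_t1", 0.7),
            PlantedEffect("disease_b", "block02_t1", -0.9),
        ],
        seed=2024,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
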