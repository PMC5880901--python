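import numpy as np
import pytest

from pancore import PanSimConfig, simulate_profile, simulate_proteomes


@pytest.fixture
def small_sim_config():
    """A small five-strain pan-genome, fast enough for sequence-level stages."""
    return PanSimConfig(
        n_strains=5,
        n_core=20,
        n_dispensable=8,
        n_unique_per_strain=2,
        mean_protein_length=150,
        within_cluster_divergence=0.1,
        seed=11,
    )


@pytest.fixture
def small_profile(small_sim_config):
    profile, truth = simulate_profile(small_sim_config)
    return profile, truth


@pytest.fixture
def identical_proteomes():
    """Five strains with zero within-cluster divergence: clustering must be exact."""
    cfg = PanSimConfig(
        n_strains=5,
        n_core=10,
        n_dispensable=4,
        n_unique_per_strain=1,
        mean_protein_length=120,
        within_cluster_divergence=0.0,
        seed=3,
    )
    return simulate_proteomes(cfg)


def random_profile(seed: int, n_strains: int = 5):
    """A modest random profile for property checks."""
    rng = np.random.default_rng(seed)
    cfg = PanSimConfig(
        n_strains=n_strains,
        n_core=int(rng.integers(5, 30)),
        n_dispensable=int(rng.integers(5, 30)),
        n_unique_per_strain=int(rng.integers(0, 5)),
        seed=seed,
    )
    return simulate_profile(cfg)[0]
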