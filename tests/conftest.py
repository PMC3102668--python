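import numpy as np
import pytest

from dgetag.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact study: 2 conditions x 4 stages, modest depth, default error rates."""
    return SimulationConfig(
        n_genes=120,
        library_depth=20_000,
        n_timepoints=4,
        profile_changes=[(1, 1, 1), (-1, -1, -1)],
        divergence_boundary=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(transcripts, refdb, truth, libraries) for the compact study."""
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def errorfree_config() -> SimulationConfig:
    """Same design with every error process switched off: the identity setting."""
    return SimulationConfig(
        n_genes=80,
        library_depth=20_000,
        n_timepoints=4,
        base_error_rate=0.0,
        adaptor_rate=0.0,
        lowq_rate=0.0,
        antisense_rate=0.0,
        catg_free_fraction=0.0,
        site_rank_probs=(1.0,),
        profile_changes=[(1, 1, 1)],
        divergence_boundary=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def errorfree_study(errorfree_config):
    return simulate_study(errorfree_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
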