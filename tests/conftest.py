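import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from latentcoding.pipeline import RunConfig, simulate_stage
from latentcoding.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def tiny_config() -> RunConfig:
    """Desk-scale configuration small enough for per-test pipelines."""
    return RunConfig(
        synthetic=SyntheticConfig(
            n_train=120,
            n_test=30,
            latent_dim=16,
            regions=(("V1", 1, 8), ("V4", 1, 8), ("IT", 1, 8)),
            image_size=64,
            seed=11,
        ),
        grid_size=6,
        folds=4,
        n_permutations=19,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """One simulated tiny experiment shared by read-only tests."""
    return simulate_stage(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
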