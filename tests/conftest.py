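import numpy as np
import pytest

from capdyn import CohortSpec, RunConfig, run_end_to_end, simulate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """A desk-scale cohort spec used across unit tests."""
    return CohortSpec(n_per_group=6, n_volumes=100, n_voxels=250, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return simulate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_study():
    """One full end-to-end study on a small cohort, reused by several tests."""
    config = RunConfig(
        cohort=CohortSpec(n_per_group=8, n_volumes=150, n_voxels=300, seed=7),
        k=3,
        n_permutations=100,
        n_boot=50,
        seed=7,
    )
    return run_end_to_end(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
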