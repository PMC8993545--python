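import numpy as np
import pytest

from sidepair import WorldConfig, generate_world, worked_fixture


@pytest.fixture(scope="session")
def fixture_world():
    """Tiny hand-written world: every value is desk-checkable."""
    return worked_fixture()


@pytest.fixture(scope="session")
def default_world():
    """One default-parameter synthetic world, shared across tests."""
    return generate_world(WorldConfig(seed=0))


def random_small_world(rng: np.random.Generator, n_drugs=None, n_side_effects=None):
    """Random tiny world for brute-force oracle comparisons (<=10 drugs)."""
    n_drugs = n_drugs or int(rng.integers(4, 11))
    n_side_effects = n_side_effects or int(rng.integers(2, 7))
    return generate_world(
        WorldConfig(
            n_drugs=n_drugs,
            n_side_effects=n_side_effects,
            n_clusters=int(rng.integers(1, 3)),
            sim_noise_sd=0.15,
            annotation_prob_in_cluster=0.8,
            annotation_prob_background=0.3,
            seed=int(rng.integers(0, 2**31)),
        )
    )
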