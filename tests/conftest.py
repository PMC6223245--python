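import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grnmf_mda import FixtureSpec, build_adjacency, generate

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Default synthetic dataset: (table, ground-truth scores, SDM)."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def fixture_adjacency(fixture_dataset):
    table, _, _ = fixture_dataset
    return build_adjacency(table)


@pytest.fixture(scope="session")
def small_dataset():
    """Smaller/denser instance for tests that re-run the full pipeline often."""
    return generate(FixtureSpec(n_microbes=30, n_diseases=12, true_rank=2,
                                density=0.12, seed=3))


def random_binary_adjacency(rng, m, n, p=0.3):
    from grnmf_mda import AdjacencyMatrix

    V = (rng.random((m, n)) < p).astype(float)
    if V.sum() == 0:
        V[0, 0] = 1.0
    return AdjacencyMatrix(
        V, [f"m{i:03d}" for i in range(m)], [f"d{j:03d}" for j in range(n)]
    )
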