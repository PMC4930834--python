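import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted():
    """A 2-module planted matrix with strong signal, plus ground truth."""
    from harmonet import FixtureSpec, make_planted_matrix

    spec = FixtureSpec(
        n_genes=30, n_attributes=20, n_modules=2,
        within_module_signal=3.0, noise_sd=1.0, seed=7,
    )
    return make_planted_matrix(spec)


@pytest.fixture
def small_ternary(rng):
    """Random sparse ternary matrix for round-trip tests."""
    from harmonet import GeneAttributeMatrix

    vals = rng.choice([-1.0, 0.0, 1.0], size=(12, 8), p=[0.15, 0.7, 0.15])
    return GeneAttributeMatrix(
        [f"g{i}" for i in range(12)], [f"t{j}" for j in range(8)], vals, "ternary"
    )


@pytest.fixture(scope="session")
def gba_fixture():
    from harmonet import make_gba_fixture

    return make_gba_fixture(
        n_pos=100, n_neg=100, n_unknown=100, n_datasets=3,
        informative_per_dataset=5, effect_size=3.0, seed=202,
    )
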