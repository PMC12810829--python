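import numpy as np
import pytest

from gashap import SyntheticSpec, generate_atlas, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_spec():
    """Miniature study: 16**3 grid, 10 regions, strong planted signal."""
    return SyntheticSpec(
        shape=(16, 16, 16), R=10, n_signal_regions=3, effect_size=3.0, n_per_class=10, seed=0
    )


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return generate_atlas(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_atlas):
    ds, signal = generate_cohort(small_atlas, small_spec)
    return ds, signal


@pytest.fixture(scope="session")
def tiny_atlas():
    """8**3 grid split into 6 Voronoi regions, for GA/morphology tests."""
    return generate_atlas(SyntheticSpec(shape=(8, 8, 8), R=6, n_signal_regions=2, seed=3))
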