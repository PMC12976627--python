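import numpy as np
import pytest

from shadowcat.irt import ModelConstants
from shadowcat.pool import ItemPool, PoolSpec, assign_strata, generate_pool


@pytest.fixture(scope="session")
def default_pool() -> ItemPool:
    """The default 360-item study pool (seeded, stratified into 3 a-strata)."""
    return assign_strata(generate_pool(PoolSpec(seed=0)), k=3)


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


def make_toy_pool(n=12, n_cats=2, seed=0, a_range=(0.6, 1.8), c_max=0.25) -> ItemPool:
    """Small random pool for brute-force comparisons."""
    rng = np.random.default_rng(seed)
    per = n // n_cats
    cats = np.repeat(np.arange(1, n_cats + 1), per)
    cats = np.concatenate([cats, np.arange(1, n - per * n_cats + 1)])
    pool = ItemPool(
        np.array([f"t{i + 1:03d}" for i in range(n)], dtype=object),
        rng.uniform(*a_range, size=n),
        rng.uniform(-1.5, 1.5, size=n),
        rng.uniform(0.0, c_max, size=n),
        cats,
    )
    return assign_strata(pool, k=min(3, n))


@pytest.fixture
def toy_pool() -> ItemPool:
    return make_toy_pool()
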