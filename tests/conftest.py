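import numpy as np
import pytest

from growthdesign import GrowthDesign, Item, ItemPool


@pytest.fixture
def unit_item() -> Item:
    return Item(a=1.0, b=0.0)


@pytest.fixture
def simple_design() -> GrowthDesign:
    """Three single-item roles with difficulties -0.5, 0, 0.5."""
    return GrowthDesign(
        (Item(1.0, -0.5),), (Item(1.0, 0.0),), (Item(1.0, 0.5),)
    )


def make_random_pool(n: int, rng: np.random.Generator) -> ItemPool:
    """Small random pool with identifiers i01, i02, ..."""
    a = rng.uniform(0.5, 2.0, size=n)
    b = rng.uniform(-2.0, 2.0, size=n)
    ids = tuple(f"i{k + 1:02d}" for k in range(n))
    return ItemPool(ids, a, b)


@pytest.fixture
def tiny_pool() -> ItemPool:
    return make_random_pool(8, np.random.default_rng(42))
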