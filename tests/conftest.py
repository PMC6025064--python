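import numpy as np
import pytest

from tdol.capacity import Capacity, MobiusCapacity, mask_size, members


def random_monotone_capacity(n: int, rng: np.random.Generator) -> Capacity:
    """Random normalized monotone set function built by monotone accretion."""
    v = np.zeros(1 << n)
    raw = rng.random(1 << n)
    for mask in sorted(range(1 << n), key=mask_size):
        if mask == 0:
            continue
        floor = max(v[mask & ~(1 << i)] for i in members(mask, n))
        v[mask] = floor + 0.3 * raw[mask]
    v /= v[(1 << n) - 1]
    return Capacity(tuple(f"a{i}" for i in range(n)), v)


def two_additive_capacity_4() -> MobiusCapacity:
    """Fixed 2-additive capacity on 4 attributes with known Shapley values."""
    m = np.zeros(16)
    m[0b0001], m[0b0010], m[0b0100], m[0b1000] = 0.25, 0.15, 0.20, 0.10
    m[0b0011], m[0b0101], m[0b1100] = 0.15, -0.05, 0.20
    return MobiusCapacity(("a0", "a1", "a2", "a3"), m, k_additive=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rand_cap():
    return random_monotone_capacity


@pytest.fixture
def cap2add():
    return two_additive_capacity_4()
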