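import numpy as np
import pytest

from pahflow import WorldSpec, generate_world
from pahflow.mrio import MRIOTable, leontief_inverse


@pytest.fixture(scope="session")
def default_world():
    """The default 4-region, 5-sector, 2-year world."""
    return generate_world(WorldSpec(seed=1))


@pytest.fixture(scope="session")
def small_spec():
    """A fast 3-region, 3-sector world spec with one producer/consumer pair."""
    return WorldSpec(n_regions=3, n_sectors=3, grid_shape=(6, 9), n_years=2,
                     producer_regions=(0,), consumer_regions=(2,), seed=7)


@pytest.fixture(scope="session")
def small_world(small_spec):
    return generate_world(small_spec)


def build_balanced_table(rng: np.random.Generator, n_regions: int, n_sectors: int,
                         zero_demand_regions: tuple[int, ...] = ()) -> MRIOTable:
    """Independent construction of a balanced table for oracle tests.

    Draws input coefficients with column sums below 1, draws nonnegative
    final demand, and solves the Leontief system so both balance identities
    hold by construction.
    """
    N = n_regions * n_sectors
    raw = rng.uniform(0.1, 1.0, size=(N, N))
    A = raw / raw.sum(axis=0, keepdims=True) * rng.uniform(0.2, 0.7, size=N)
    Fd = rng.uniform(0.5, 2.0, size=(N, n_regions))
    for m in zero_demand_regions:
        Fd[:, m] = 0.0
    x = leontief_inverse(A) @ Fd.sum(axis=1)
    Z = A * x[None, :]
    v = x - Z.sum(axis=0)
    t = MRIOTable(Z=Z, Fd=Fd, v=v, x=x, n_regions=n_regions, n_sectors=n_sectors)
    t.validate()
    return t
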