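import numpy as np
import pytest

from passar import (
    AbundanceTable,
    PlacementSpec,
    PoolSpec,
    SampleAreas,
    generate_pool,
    simulate_passive_sampling,
)


@pytest.fixture
def small_table() -> AbundanceTable:
    """3 samples x 4 taxa with simple hand-checkable counts."""
    counts = np.array(
        [
            [5, 3, 2, 0],
            [1, 0, 0, 4],
            [2, 2, 2, 2],
        ]
    )
    return AbundanceTable(("sA", "sB", "sC"), ("t1", "t2", "t3", "t4"), counts)


@pytest.fixture
def equal_areas() -> SampleAreas:
    return SampleAreas({"sA": 0.36, "sB": 0.36, "sC": 0.36})


@pytest.fixture(scope="session")
def sim_table():
    """A mid-sized passive-sampling table (8 islands, 600-species pool)."""
    pool = generate_pool(PoolSpec(n_species=600, total_individuals=30000, seed=11))
    placement = PlacementSpec((0.36,) * 8, seed=11)
    table = simulate_passive_sampling(pool, placement)
    areas = SampleAreas({s: 0.36 for s in table.sample_ids})
    return pool, placement, table, areas
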