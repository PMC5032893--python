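import numpy as np
import pandas as pd
import pytest

import isoregion as ir


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world (3 regions, 18 areas, 400 individuals)."""
    params = ir.GeneratorParams(
        n_regions=3, areas_per_region=6, n_individuals=400,
        n_region_surnames=30, n_common_surnames=20,
    )
    return ir.generate_world(params, seed=11)


@pytest.fixture(scope="session")
def small_taxonomy(small_world):
    areas, counts, sample, truth = small_world
    eta = ir.compute_isonymy(counts)
    dist = ir.isonymy_to_distance(eta)
    w = areas.df.set_index("area_id")["population"]
    return ir.ward_taxonomy(dist, w[dist.ids].to_numpy(float))


@pytest.fixture(scope="session")
def small_linked(small_world, small_taxonomy):
    areas, counts, sample, truth = small_world
    return ir.link_sample(sample, areas, small_taxonomy, list(range(2, 9)), seed=5)


@pytest.fixture
def toy_areas():
    return ir.AreaTable(pd.DataFrame({
        "area_id": ["a", "b", "c", "d", "e"],
        "x": [0.0, 1000.0, 2000.0, 10_000.0, 11_000.0],
        "y": [0.0, 0.0, 0.0, 0.0, 0.0],
        "population": [900, 500, 300, 2000, 100],
        "rural": [True, True, False, True, False],
        "origin_class": ["anglo-saxon", "anglo-saxon", "norman", "scottish", "scottish"],
    }))


@pytest.fixture
def toy_counts(toy_areas):
    return ir.SurnameCounts(pd.DataFrame({
        "area_id": ["a", "a", "b", "c", "d", "d", "e"],
        "surname": ["Smith", "Jones", "Smith", "Evans", "Mac", "Smith", "Mac"],
        "count": [10, 5, 7, 3, 20, 2, 4],
    }), areas=toy_areas)
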