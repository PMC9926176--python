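import numpy as np
import pandas as pd
import pytest

from basinbio.basins import BasinHierarchy
from basinbio.ranges import BayAreaParams, RangeModel, Stratum
from basinbio.synth import (
    SyntheticConfig,
    presence_from_ranges,
    simulate_basins,
    simulate_occurrences,
    simulate_ranges,
    simulate_tree,
)
from basinbio.trees import IndexedTree


@pytest.fixture
def tiny_hierarchy() -> BasinHierarchy:
    """Two bioregions, one level-4 catchment each, 3 + 2 level-5 basins."""
    table = pd.DataFrame(
        {
            "basin_id": ["b1", "b2", "b3", "c1", "c2"],
            "level4_id": ["L1", "L1", "L1", "L2", "L2"],
            "bioregion_id": ["R1", "R1", "R1", "R2", "R2"],
            "area_km2": [100.0, 200.0, 400.0, 800.0, 1600.0],
        }
    )
    footprints = {
        "b1": (0.0, 0.0, 1.0, 1.0),
        "b2": (1.0, 0.0, 2.0, 1.0),
        "b3": (2.0, 0.0, 3.0, 1.0),
        "c1": (0.0, 1.0, 1.0, 2.0),
        "c2": (1.0, 1.0, 2.0, 2.0),
    }
    return BasinHierarchy(table, footprints)


@pytest.fixture
def five_tip_tree() -> IndexedTree:
    return IndexedTree.from_newick(
        "(((a:1.0,b:1.0):1.5,c:2.5):1.5,(d:3.0,e:3.0):1.0);"
    )


@pytest.fixture(scope="session")
def gapfill_scenario():
    """60 basins, 300 species, ten-fold effort gradient: the gap-fill testbed."""
    cfg = SyntheticConfig(seed=42, n_tips=300)
    hierarchy = simulate_basins(cfg)
    tree = simulate_tree(cfg)
    model = RangeModel(
        hierarchy.bioregion_ids, cfg.strata, BayAreaParams(cfg.true_d, cfg.true_e)
    )
    history = simulate_ranges(tree, model, cfg.rng("ranges"))
    presence = presence_from_ranges(
        history.tip_ranges, hierarchy, cfg.rng("presence"), cfg.basin_occupancy
    )
    occurrences, manifest, tables = simulate_occurrences(hierarchy, presence, cfg)
    return {
        "config": cfg,
        "hierarchy": hierarchy,
        "tree": tree,
        "history": history,
        "true_presence": presence,
        "occurrences": occurrences,
        "manifest": manifest,
        "tables": tables,
    }


def uniform_stratum(n_areas: int, start: float = 300.0) -> list[Stratum]:
    return [Stratum(start, 0.0, np.ones((n_areas, n_areas)))]
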