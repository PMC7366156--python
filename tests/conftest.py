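import numpy as np
import pandas as pd
import pytest

from nfisim import LandscapeConfig, simulate_landscape


@pytest.fixture(scope="session")
def forest_landscape():
    """A fully forested 16 ha landscape used by measurement/estimation tests.

    The alpine threshold is set above the elevation ceiling so the whole
    extent is lowland (stratum 1) and forest_fraction 1 makes every stand
    forest: tests that need trees everywhere don't depend on the stand
    lottery.
    """
    cfg = LandscapeConfig(
        extent=(0.0, 0.0, 400.0, 400.0),
        cell_size=50.0,
        seed=3,
        alpine_threshold_m=2000.0,
        forest_fraction={1: 1.0, 2: 0.1},
    )
    return simulate_landscape(cfg)


class StubLandscape:
    """Hand-built landscape satisfying the measurement protocol interface."""

    def __init__(self, trees=None, deadwood=None, land_use="forest"):
        self.trees = trees if trees is not None else empty_trees()
        self.deadwood = deadwood if deadwood is not None else empty_deadwood()
        self._land_use = land_use

    def stand_attributes_at(self, x, y):
        from nfisim import StandAttributes

        return StandAttributes(land_use=self._land_use)

    def berry_cover_at(self, x, y):
        return {"bilberry": 0.2, "lingonberry": 0.1}

    def dropping_count_at(self, x, y, area_m2):
        return 0

    def vegetation_type_at(self, x, y):
        return "bilberry_woodland"


def empty_trees():
    return pd.DataFrame(
        columns=["tree_id", "x", "y", "species", "species_group", "dbh_cm",
                 "height_m", "age", "status", "standing"]
    )


def empty_deadwood():
    return pd.DataFrame(
        columns=["x", "y", "species_group", "decay_class", "length_m",
                 "azimuth_deg", "d_root_cm", "d_cross_cm", "d_top_cm"]
    )


def make_trees(rows):
    """Tree table from (x, y, species, dbh, height) tuples (live, standing)."""
    from nfisim import species_group

    recs = []
    for i, (x, y, sp, dbh, h) in enumerate(rows):
        recs.append({
            "tree_id": i, "x": x, "y": y, "species": sp,
            "species_group": species_group(sp), "dbh_cm": dbh, "height_m": h,
            "age": 50.0, "status": "live", "standing": True,
        })
    return pd.DataFrame(recs)


@pytest.fixture
def stub_landscape_factory():
    return StubLandscape
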