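"""Synthetic forest landscapes with the statistical structure the
inventory design assumes.

The generator produces, from a seed: an elevation-like covariate field
(Gaussian random field with a spherical variogram on the logit scale,
mapped affinely to [0, 1500] m); a space-filling stand mosaic (Voronoi
tessellation of Poisson seed points); per-stand attributes (stratum from
the elevation threshold, forest/non-forest, dominant species drawn from
stratum-level mixes, site index, age, maturity class); individual trees
(homogeneous Poisson positions within stands, two-parameter Weibull dbh,
heights from the h-dbh allometry with lognormal scatter, 90% species
fidelity to the stand's dominant group); downed deadwood pieces; and
remeasurement dynamics (annual growth, mortality, stand-level harvest,
ingrowth at the 5 cm threshold).

Default rates emulate the published stratum-level species mixes and forest
proportions of the 2014-2018 inventory cycle; densities and the dbh
distribution are generic boreal values.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .dendrometry import AllometrySet, StandAttributes, species_group
from .raster import Raster
from .variogram import SphericalVariogram, simulate_grid_field

__all__ = ["LandscapeConfig", "Landscape", "simulate_elevation", "simulate_forest",
           "simulate_remeasurement", "simulate_landscape"]

#: Stratum-level (spruce, pine, deciduous) shares of forest area and the
#: unstocked fraction, emulating the published 2014-2018 cycle figures.
DEFAULT_SPECIES_MIX = {
    1: (0.340, 0.337, 0.318, 0.006),
    2: (0.036, 0.081, 0.878, 0.005),
    3: (0.000, 0.642, 0.358, 0.000),
    4: (0.000, 0.042, 0.949, 0.008),
}
DEFAULT_FOREST_FRACTION = {1: 0.664, 2: 0.095, 3: 0.80, 4: 0.205}

_GROUP_SPECIES = {"spruce": "spruce", "pine": "pine", "deciduous": "birch"}
_VEG_TYPES = ("bilberry_woodland", "heather", "tall_herb", "low_herb", "lichen")


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic landscape; see module docstring for defaults.

    ``extent`` is (xmin, ymin, xmax, ymax) in projected metres.  Dynamics
    rates: ``growth_mean/sd`` in cm/yr, ``mortality_prob`` per tree-year,
    ``harvest_prob_5yr`` per stand and 5-year cycle, ``ingrowth_per_ha_yr``
    stems crossing the 5 cm threshold.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    cell_size: float = 16.0
    elevation_variogram: SphericalVariogram = field(
        default_factory=lambda: SphericalVariogram(0.0, 0.73, 5600.0)
    )
    elevation_max_m: float = 1500.0
    alpine_threshold_m: float = 900.0
    species_mix: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_MIX))
    forest_fraction: dict = field(default_factory=lambda: dict(DEFAULT_FOREST_FRACTION))
    mean_stand_area_ha: float = 2.0
    stems_per_ha: dict = field(
        default_factory=lambda: {1: 50.0, 2: 1100.0, 3: 900.0, 4: 600.0, 5: 400.0}
    )
    small_stems_per_ha: float = 400.0
    dbh_weibull_shape: float = 1.8
    dbh_weibull_scale_cm: float = 10.0
    height_lognorm_sd: float = 0.08
    species_fidelity: float = 0.9
    deadwood_per_ha: float = 20.0
    deadwood_diam_weibull: tuple[float, float] = (1.6, 8.0)
    standing_dead_fraction: float = 0.03
    growth_mean_cm_yr: float = 0.3
    growth_sd_cm_yr: float = 0.1
    mortality_prob: float = 0.005
    harvest_prob_5yr: float = 0.05
    ingrowth_per_ha_yr: float = 5.0
    epoch: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive area")
        for s, mix in self.species_mix.items():
            if abs(sum(mix[:3]) + mix[3] - 1.0) > 0.02 and sum(mix[:3]) > 0:
                raise ValueError(f"species mix of stratum {s} must sum to ~1")
        for name in ("mortality_prob", "harvest_prob_5yr", "species_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dbh_weibull_shape <= 0 or self.dbh_weibull_scale_cm <= 0:
            raise ValueError("Weibull parameters must be > 0")


_STAND_COLS = ["stand_id", "stratum", "land_use", "dominant_species", "si_class",
               "stand_age", "maturity_class", "stocking_flag", "vegetation_type",
               "bilberry", "lingonberry", "droppings_per_ha", "area_m2"]

_TREE_COLS = ["tree_id", "x", "y", "stand_id", "species", "species_group",
              "dbh_cm", "height_m", "height_factor", "age", "status", "standing",
              "death_epoch", "removal_epoch"]


@dataclass
class Landscape:
    """One realization of the synthetic landscape at a calendar epoch."""

    config: LandscapeConfig
    elevation: Raster
    stands: pd.DataFrame  # one row per stand (attributes, area)
    stand_geoms: list  # shapely polygons, index-aligned with `stands`
    trees: pd.DataFrame
    deadwood: pd.DataFrame
    epoch: int

    def __post_init__(self) -> None:
        self._tree_index = STRtree(self.stand_geoms)

    def stand_index_at(self, x: float, y: float) -> int:
        hits = self._tree_index.query(Point(x, y), predicate="intersects")
        if len(hits) == 0:
            raise ValueError("point outside every stand polygon")
        return int(hits[0])

    def _stand_row(self, x, y) -> pd.Series:
        return self.stands.iloc[self.stand_index_at(x, y)]

    def stand_attributes_at(self, x: float, y: float) -> StandAttributes:
        r = self._stand_row(x, y)
        return StandAttributes(
            site_index_class=int(r["si_class"]),
            stand_age=float(r["stand_age"]),
            maturity_class=int(r["maturity_class"]),
            stocking_flag=r["stocking_flag"],
            dominant_species=r["dominant_species"],
            land_use=r["land_use"],
        )

    def forest_at(self, x: float, y: float) -> bool:
        return self._stand_row(x, y)["land_use"] == "forest"

    def vegetation_type_at(self, x: float, y: float) -> str:
        return self._stand_row(x, y)["vegetation_type"]

    def berry_cover_at(self, x: float, y: float) -> dict[str, float]:
        r = self._stand_row(x, y)
        return {"bilberry": float(r["bilberry"]), "lingonberry": float(r["lingonberry"])}

    def dropping_count_at(self, x: float, y: float, plot_area_m2: float) -> int:
        r = self._stand_row(x, y)
        return int(round(r["droppings_per_ha"] * plot_area_m2 / 1e4))

    # ---- population truths for design-based checks ----

    def forest_area_m2(self) -> float:
        return float(self.stands.loc[self.stands["land_use"] == "forest", "area_m2"].sum())

    def live_trees(self) -> pd.DataFrame:
        return self.trees[(self.trees["status"] == "live") & (self.trees["dbh_cm"] >= 5.0)]

    def total_volume_m3(self, allometry: AllometrySet | None = None) -> float:
        allo = allometry or AllometrySet()
        t = self.live_trees()
        if len(t) == 0:
            return 0.0
        v = [float(allo.volume(sp, d, h)) for sp, d, h in
             zip(t["species"], t["dbh_cm"], t["height_m"])]
        return float(np.sum(v))

    def downed_deadwood_volume_m3(self) -> float:
        """Truth for line-intersect checks: conical-frustum piece volumes."""
        p = self.deadwood
        if len(p) == 0:
            return 0.0
        r0 = p["d_root_cm"].to_numpy() / 200.0
        r1 = p["d_top_cm"].to_numpy() / 200.0
        return float(np.sum(np.pi / 3.0 * p["length_m"].to_numpy() * (r0**2 + r0 * r1 + r1**2)))


def simulate_elevation(config: LandscapeConfig, rng: np.random.Generator | None = None) -> Raster:
    """Elevation-like covariate: spherical-variogram Gaussian field on the
    logit scale, back-transformed by the logistic map to [0, elevation_max].

    Deterministic given ``config.seed``; warns when the extent is small
    relative to the variogram range (range then not identifiable from the
    realization).
    """
    vg = config.elevation_variogram
    if vg.nugget < 0 or vg.sill < 0 or vg.range_m <= 0:
        raise ValueError("invalid variogram parameters")
    rng = rng or np.random.default_rng(config.seed)
    field_su, xs, ys = simulate_grid_field(config.extent, config.cell_size, vg, rng)
    elev = config.elevation_max_m * expit(field_su)
    return Raster.from_south_up(elev, config.extent[0], config.extent[1], config.cell_size)


def _voronoi_stands(config: LandscapeConfig, rng: np.random.Generator) -> list:
    xmin, ymin, xmax, ymax = config.extent
    area_ha = (xmax - xmin) * (ymax - ymin) / 1e4
    n = max(rng.poisson(area_ha / config.mean_stand_area_ha), 1)
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
    )
    env = box(xmin, ymin, xmax, ymax)
    cells = voronoi_diagram(MultiPoint([tuple(p) for p in pts]), envelope=env)
    geoms = [g.intersection(env) for g in cells.geoms]
    return [g for g in geoms if not g.is_empty and g.area > 0]


def _sample_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a (convex) polygon by bounding-box rejection."""
    out = np.empty((0, 2))
    xmin, ymin, xmax, ymax = poly.bounds
    while len(out) < n:
        m = max(int((n - len(out)) * 2.5), 16)
        cand = np.column_stack([rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)])
        keep = [poly.covers(Point(x, y)) for x, y in cand]
        out = np.vstack([out, cand[keep]])
    return out[:n]


def simulate_forest(
    config: LandscapeConfig,
    elevation: Raster,
    rng: np.random.Generator | None = None,
    include_trees: bool = True,
) -> Landscape:
    """Populate stands, trees, and deadwood on top of an elevation raster."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    allo = AllometrySet()
    geoms = _voronoi_stands(config, rng)
    maturity_entry = {2: 1, 3: 30, 4: 70, 5: 100}

    stand_rows = []
    tree_frames = []
    dead_frames = []
    tree_id = 0
    for sid, poly in enumerate(geoms):
        c = poly.representative_point()
        elev = float(elevation.sample(
            np.clip(c.x, elevation.x0 + 1e-6, elevation.extent[2] - 1e-6),
            np.clip(c.y, elevation.y0 + 1e-6, elevation.extent[3] - 1e-6),
        ))
        stratum = 2 if elev >= config.alpine_threshold_m else 1
        mix = config.species_mix.get(stratum, DEFAULT_SPECIES_MIX[1])
        is_forest = rng.random() < config.forest_fraction.get(stratum, 0.5)
        land_use = "forest" if is_forest else "other"
        unstocked = is_forest and rng.random() < mix[3]
        p3 = np.asarray(mix[:3], dtype=float)
        dominant = (
            ("spruce", "pine", "deciduous")[rng.choice(3, p=p3 / p3.sum())]
            if is_forest and p3.sum() > 0
            else "deciduous"
        )
        si = int(rng.choice((8, 11, 14, 17, 20), p=(0.15, 0.25, 0.3, 0.2, 0.1)))
        if unstocked:
            maturity, age = 1, 0.0
        else:
            maturity = int(rng.choice((2, 3, 4, 5), p=(0.3, 0.3, 0.2, 0.2)))
            lo = maturity_entry[maturity]
            hi = {2: 40, 3: 70, 4: 100, 5: 160}[maturity]
            age = float(rng.uniform(lo, hi))
        stand_rows.append(
            {
                "stand_id": sid,
                "stratum": stratum,
                "land_use": land_use,
                "dominant_species": _GROUP_SPECIES[dominant] if is_forest else "none",
                "si_class": si,
                "stand_age": age if is_forest else 0.0,
                "maturity_class": maturity if is_forest else 1,
                "stocking_flag": "sufficiently",
                "vegetation_type": _VEG_TYPES[rng.choice(len(_VEG_TYPES))],
                "bilberry": float(rng.beta(1.5, 6.0)),
                "lingonberry": float(rng.beta(1.2, 8.0)),
                "droppings_per_ha": float(rng.gamma(2.0, 10.0)),
                "area_m2": poly.area,
            }
        )
        if not (include_trees and is_forest and not unstocked):
            continue

        area_ha = poly.area / 1e4
        n_big = rng.poisson(config.stems_per_ha.get(maturity, 500.0) * area_ha)
        n_small = rng.poisson(config.small_stems_per_ha * area_ha)
        n_dead = rng.poisson(config.deadwood_per_ha * area_ha)
        if n_big + n_small > 0:
            pos = _sample_in_polygon(poly, n_big + n_small, rng)
            dom_draw = rng.random(n_big + n_small) < config.species_fidelity
            others = [g for g in ("spruce", "pine", "deciduous") if g != dominant]
            grp = np.where(dom_draw, dominant, rng.choice(others, n_big + n_small))
            species = np.array([_GROUP_SPECIES[g] for g in grp])
            dbh = np.concatenate([
                5.0 + config.dbh_weibull_scale_cm * rng.weibull(config.dbh_weibull_shape, n_big),
                rng.uniform(0.3, 5.0, n_small),
            ])
            hfac = np.exp(rng.normal(0.0, config.height_lognorm_sd, n_big + n_small))
            h_model = np.array([float(allo.height(s, d)) for s, d in zip(species, dbh)])
            height = np.where(dbh >= 5.0, h_model * hfac, 0.3 + dbh * 0.35)
            ages = np.clip(rng.normal(age, max(age * 0.15, 1.0), n_big + n_small), 1, None)
            status = np.where(
                (dbh >= 5.0) & (rng.random(n_big + n_small) < config.standing_dead_fraction),
                "dead", "live",
            )
            tree_frames.append(pd.DataFrame({
                "tree_id": np.arange(tree_id, tree_id + n_big + n_small),
                "x": pos[:, 0], "y": pos[:, 1], "stand_id": sid,
                "species": species, "species_group": grp,
                "dbh_cm": dbh, "height_m": height, "height_factor": hfac,
                "age": ages, "status": status, "standing": True,
                "death_epoch": np.where(status == "dead", config.epoch, -1),
                "removal_epoch": -1,
            }))
            tree_id += n_big + n_small
        if n_dead > 0:
            pos = _sample_in_polygon(poly, n_dead, rng)
            shape_w, scale_w = config.deadwood_diam_weibull
            d_root = 5.0 + scale_w * rng.weibull(shape_w, n_dead)
            d_top = d_root * rng.uniform(0.2, 0.6, n_dead)
            dead_frames.append(pd.DataFrame({
                "x": pos[:, 0], "y": pos[:, 1], "stand_id": sid,
                "species_group": rng.choice(("spruce", "pine", "deciduous"), n_dead),
                "decay_class": rng.integers(1, 6, n_dead),
                "length_m": rng.uniform(2.0, 10.0, n_dead),
                "azimuth_deg": rng.uniform(0.0, 360.0, n_dead),
                "d_root_cm": d_root,
                "d_cross_cm": (d_root + d_top) / 2.0,
                "d_top_cm": d_top,
            }))

    trees = (
        pd.concat(tree_frames, ignore_index=True)
        if tree_frames
        else pd.DataFrame(columns=_TREE_COLS)
    )
    deadwood = (
        pd.concat(dead_frames, ignore_index=True)
        if dead_frames
        else pd.DataFrame(columns=["x", "y", "stand_id", "species_group", "decay_class",
                                   "length_m", "azimuth_deg", "d_root_cm", "d_cross_cm",
                                   "d_top_cm"])
    )
    return Landscape(
        config=config,
        elevation=elevation,
        stands=pd.DataFrame(stand_rows),
        stand_geoms=geoms,
        trees=trees,
        deadwood=deadwood,
        epoch=config.epoch,
    )


def simulate_landscape(config: LandscapeConfig, include_trees: bool = True) -> Landscape:
    """Convenience: elevation + forest in one call, seeded by the config."""
    rng = np.random.default_rng(config.seed)
    elevation = simulate_elevation(config, rng)
    return simulate_forest(config, elevation, rng, include_trees=include_trees)


def simulate_remeasurement(landscape: Landscape, years: int) -> Landscape:
    """Advance the landscape by ``years`` growing seasons.

    Annual steps: surviving stems grow by a normal increment (cm/yr,
    truncated at 0), die with the configured annual probability, whole
    stands are harvested (all live stems flagged removed, age reset) with
    the 5-year stand probability converted to an annual rate, and ingrowth
    appears at the 5 cm threshold.  Heights track the h-dbh curve through
    each tree's persistent lognormal factor.  Deterministic given the
    originating config seed and epoch.
    """
    if years <= 0:
        raise ValueError("years must be > 0")
    cfg = landscape.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, landscape.epoch, years]))
    allo = AllometrySet()
    trees = landscape.trees.copy()
    stands = landscape.stands.copy()
    p_harv_yr = 1.0 - (1.0 - cfg.harvest_prob_5yr) ** (1.0 / 5.0)
    next_id = int(trees["tree_id"].max()) + 1 if len(trees) else 0

    forest_sids = stands.loc[stands["land_use"] == "forest", "stand_id"].to_numpy()
    new_rows = []
    for step in range(years):
        year = landscape.epoch + step + 1
        big = (trees["status"] == "live") & (trees["dbh_cm"] >= 5.0)
        n_big_live = int(big.sum())
        if n_big_live:
            growth = np.clip(rng.normal(cfg.growth_mean_cm_yr, cfg.growth_sd_cm_yr, n_big_live), 0.0, None) \
                if cfg.growth_sd_cm_yr > 0 else np.full(n_big_live, cfg.growth_mean_cm_yr)
            trees.loc[big, "dbh_cm"] = trees.loc[big, "dbh_cm"].to_numpy() + growth
        # small trees grow too, eventually crossing the 5 cm threshold
        small = (trees["status"] == "live") & (trees["dbh_cm"] < 5.0)
        if small.any():
            trees.loc[small, "dbh_cm"] = trees.loc[small, "dbh_cm"].to_numpy() + cfg.growth_mean_cm_yr
        live = trees["status"] == "live"
        n_live = int(live.sum())
        if n_live and cfg.mortality_prob > 0:
            dies = rng.random(n_live) < cfg.mortality_prob
            idx = trees.index[live][dies]
            trees.loc[idx, ["status", "death_epoch"]] = ["dead", year]

        harvested = forest_sids[rng.random(len(forest_sids)) < p_harv_yr]
        if len(harvested):
            m = trees["stand_id"].isin(harvested) & (trees["status"] == "live")
            trees.loc[m, ["status", "removal_epoch"]] = ["removed", year]
            trees.loc[m, "standing"] = False
            srows = stands["stand_id"].isin(harvested)
            stands.loc[srows, ["stand_age", "maturity_class"]] = [0.0, 1]

        for sid in forest_sids:
            if sid in harvested:
                continue
            poly = landscape.stand_geoms[int(stands.index[stands["stand_id"] == sid][0])]
            n_in = rng.poisson(cfg.ingrowth_per_ha_yr * poly.area / 1e4)
            if n_in == 0:
                continue
            pos = _sample_in_polygon(poly, n_in, rng)
            dom = stands.loc[stands["stand_id"] == sid, "dominant_species"].iloc[0]
            grp = species_group(dom if dom != "none" else "birch")
            species = _GROUP_SPECIES[grp]
            dbh = 5.0 + rng.uniform(0.0, cfg.growth_mean_cm_yr, n_in)
            hfac = np.exp(rng.normal(0.0, cfg.height_lognorm_sd, n_in))
            for k in range(n_in):
                new_rows.append({
                    "tree_id": next_id, "x": pos[k, 0], "y": pos[k, 1], "stand_id": sid,
                    "species": species, "species_group": grp, "dbh_cm": dbh[k],
                    "height_m": float(allo.height(species, dbh[k])) * hfac[k],
                    "height_factor": hfac[k], "age": 10.0, "status": "live",
                    "standing": True, "death_epoch": -1, "removal_epoch": -1,
                })
                next_id += 1

    if new_rows:
        trees = pd.concat([trees, pd.DataFrame(new_rows)], ignore_index=True)
    # heights follow the h-dbh curve through the persistent per-tree factor
    big = trees["dbh_cm"] >= 5.0
    if big.any():
        h_model = np.array([
            float(allo.height(s, d))
            for s, d in zip(trees.loc[big, "species"], trees.loc[big, "dbh_cm"])
        ])
        trees.loc[big, "height_m"] = h_model * trees.loc[big, "height_factor"].to_numpy()
    trees.loc[trees["dbh_cm"] < 5.0, "height_m"] = 0.3 + trees.loc[trees["dbh_cm"] < 5.0, "dbh_cm"] * 0.35
    trees["age"] = trees["age"] + years
    unharvested = stands["stand_age"] > 0
    stands.loc[unharvested, "stand_age"] = stands.loc[unharvested, "stand_age"] + years

    return Landscape(
        config=cfg,
        elevation=landscape.elevation,
        stands=stands,
        stand_geoms=landscape.stand_geoms,
        trees=trees,
        deadwood=landscape.deadwood.copy(),
        epoch=landscape.epoch + years,
    )
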