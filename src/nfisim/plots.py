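"""Field measurement protocol at one permanent plot location.

The plot is a nest of concentric sampling units around a common centre:
trees with dbh >= 5 cm are callipered on a 250 m^2 circle (8.92 m radius);
stand attributes are assessed on 0.1 ha and woodland key habitats on 0.2 ha;
regeneration is counted on five 16 m^2 subplots (centre + 12 m in the
cardinal directions); small trees (dbh < 5 cm) and berry cover sit 5 m out
in the cardinal directions; downed deadwood is recorded along two 18 m
transects (E-W and N-S) through the centre; animal droppings on 100 m^2.

Where the plot centre falls near a stand border the plot is split into at
most two parts along a chord, provided the smaller part is at least
37.5 m^2 (15% of the plot) and the stands differ in maturity class, site
index, growing stock, or land use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint

from .dendrometry import StandAttributes, species_group

__all__ = [
    "PlotGeometry",
    "PlotPart",
    "PlotObservation",
    "ChiHabitatRecord",
    "layout_plot",
    "circular_segment_area",
    "split_plot",
    "attributes_differ",
    "measure_plot",
    "HTreeSelection",
    "select_h_trees",
    "angle_count_limit",
    "classify_chi_habitats",
    "ChiConfig",
    "BAF_LADDER",
]

TREE_PLOT_AREA_M2 = 250.0
STAND_PLOT_AREA_M2 = 1000.0
HABITAT_PLOT_AREA_M2 = 2000.0
REGEN_SUBPLOT_AREA_M2 = 16.0
SMALLTREE_SUBPLOT_RADIUS_M = 1.3
BERRY_QUADRAT_AREA_M2 = 0.25
TRANSECT_LENGTH_M = 18.0
DROPPING_PLOT_AREA_M2 = 100.0
MIN_SPLIT_PART_M2 = 0.15 * TREE_PLOT_AREA_M2  # 37.5 m^2

BAF_LADDER = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 9.0)  # m^2/ha
MAX_H_TREES = 10

_CARDINALS = {"N": (0.0, 1.0), "E": (1.0, 0.0), "S": (0.0, -1.0), "W": (-1.0, 0.0)}


def _radius(area_m2: float) -> float:
    return math.sqrt(area_m2 / math.pi)


@dataclass(frozen=True)
class PlotGeometry:
    center: tuple[float, float]
    tree_plot_radius: float = field(default_factory=lambda: _radius(TREE_PLOT_AREA_M2))
    stand_plot_radius: float = field(default_factory=lambda: _radius(STAND_PLOT_AREA_M2))
    habitat_plot_radius: float = field(default_factory=lambda: _radius(HABITAT_PLOT_AREA_M2))
    regen_subplot_radius: float = field(default_factory=lambda: _radius(REGEN_SUBPLOT_AREA_M2))
    smalltree_subplot_radius: float = SMALLTREE_SUBPLOT_RADIUS_M
    regen_offset_m: float = 12.0
    smalltree_offset_m: float = 5.0
    transect_length_m: float = TRANSECT_LENGTH_M
    dropping_plot_radius: float = field(default_factory=lambda: _radius(DROPPING_PLOT_AREA_M2))

    def regen_subplot_centers(self) -> dict[str, tuple[float, float]]:
        cx, cy = self.center
        out = {"C": (cx, cy)}
        for k, (ux, uy) in _CARDINALS.items():
            out[k] = (cx + ux * self.regen_offset_m, cy + uy * self.regen_offset_m)
        return out

    def smalltree_subplot_centers(self) -> dict[str, tuple[float, float]]:
        cx, cy = self.center
        return {
            k: (cx + ux * self.smalltree_offset_m, cy + uy * self.smalltree_offset_m)
            for k, (ux, uy) in _CARDINALS.items()
        }

    def transects(self) -> dict[str, LineString]:
        cx, cy = self.center
        h = self.transect_length_m / 2.0
        return {
            "EW": LineString([(cx - h, cy), (cx + h, cy)]),
            "NS": LineString([(cx, cy - h), (cx, cy + h)]),
        }


def layout_plot(center) -> PlotGeometry:
    """Instantiate the full nested plot geometry at ``center``."""
    return PlotGeometry(center=(float(center[0]), float(center[1])))


@dataclass
class PlotPart:
    part_id: int  # 1 or 2
    area_m2: float
    stand_attributes: StandAttributes
    # chord as (signed distance from centre along the normal, normal azimuth
    # in degrees); None for an unsplit plot
    boundary: tuple[float, float] | None = None


def circular_segment_area(radius: float, chord_distance: float) -> float:
    """Area of the circular segment beyond a chord at ``chord_distance``
    from the centre (closed form)."""
    d = abs(chord_distance)
    if d >= radius:
        return 0.0
    return radius**2 * math.acos(d / radius) - d * math.sqrt(radius**2 - d**2)


def attributes_differ(a: StandAttributes, b: StandAttributes) -> bool:
    """Split trigger: stands markedly different in maturity class, site
    index, or land use (growing-stock contrast is folded into maturity)."""
    return (
        a.maturity_class != b.maturity_class
        or a.site_index_class != b.site_index_class
        or a.land_use != b.land_use
    )


def split_plot(
    geometry: PlotGeometry,
    chord_distance: float,
    chord_azimuth_deg: float,
    attributes_center_side: StandAttributes,
    attributes_far_side: StandAttributes,
) -> list[PlotPart]:
    """Split the 250 m^2 plot along a chord if the protocol allows it.

    The chord lies ``chord_distance`` metres from the centre along the
    normal direction ``chord_azimuth_deg``.  A split happens only when the
    cut-off segment is at least 37.5 m^2 on each side *and* the stand
    attributes differ; otherwise one full-plot part is returned carrying the
    centre-side attributes.
    """
    r = geometry.tree_plot_radius
    seg = circular_segment_area(r, chord_distance)
    full = TREE_PLOT_AREA_M2
    if (
        seg >= MIN_SPLIT_PART_M2
        and (full - seg) >= MIN_SPLIT_PART_M2
        and attributes_differ(attributes_center_side, attributes_far_side)
    ):
        boundary = (float(chord_distance), float(chord_azimuth_deg))
        return [
            PlotPart(1, full - seg, attributes_center_side, boundary),
            PlotPart(2, seg, attributes_far_side, boundary),
        ]
    return [PlotPart(1, full, attributes_center_side, None)]


def _part_of(geometry: PlotGeometry, parts: list[PlotPart], x, y) -> np.ndarray:
    """Part id for point(s) relative to the split chord (part 2 = beyond)."""
    if len(parts) == 1 or parts[0].boundary is None:
        return np.ones(np.size(x), dtype=int)
    dist, az = parts[0].boundary
    ux, uy = math.sin(math.radians(az)), math.cos(math.radians(az))
    cx, cy = geometry.center
    proj = (np.asarray(x) - cx) * ux + (np.asarray(y) - cy) * uy
    return np.where(proj > dist, 2, 1)


@dataclass
class PlotObservation:
    """Everything recorded at one plot visit."""

    plot_id: object
    geometry: PlotGeometry
    parts: list[PlotPart]
    trees: pd.DataFrame  # dbh >= 5 cm on the 250 m^2 plot
    habitat_trees: pd.DataFrame  # trees on the 0.2 ha habitat plot
    smalltrees: pd.DataFrame
    regen: pd.DataFrame
    deadwood: pd.DataFrame
    berry: pd.DataFrame
    droppings: int
    vegetation_type: str | None = None


_TREE_COLS = [
    "tree_id", "species", "species_group", "dbh_cm", "height_m", "age",
    "status", "standing", "distance_m", "azimuth_deg", "part_id",
]


def _tally_trees(trees: pd.DataFrame, cx: float, cy: float, radius: float, min_dbh: float) -> pd.DataFrame:
    dx = trees["x"].to_numpy() - cx
    dy = trees["y"].to_numpy() - cy
    dist = np.hypot(dx, dy)
    keep = (dist <= radius) & (trees["dbh_cm"].to_numpy() >= min_dbh)
    out = trees.loc[keep].copy()
    out["distance_m"] = dist[keep]
    out["azimuth_deg"] = np.degrees(np.arctan2(dx[keep], dy[keep])) % 360.0
    return out


def measure_plot(landscape, geometry: PlotGeometry, parts: list[PlotPart] | None = None, plot_id=None) -> PlotObservation:
    """Carry out the full plot protocol against a (synthetic) landscape.

    ``landscape`` provides ``trees`` (all stems, including small trees and
    standing dead) and ``deadwood`` (downed pieces) tables plus stand
    attributes; see :mod:`nfisim.landscape`.  Inclusion on circular units is
    distance <= radius (closed disc), dbh threshold inclusive at 5.00 cm.
    """
    cx, cy = geometry.center
    if parts is None:
        parts = [PlotPart(1, TREE_PLOT_AREA_M2, landscape.stand_attributes_at(cx, cy))]
    trees = landscape.trees

    tally = _tally_trees(trees, cx, cy, geometry.tree_plot_radius, 5.0)
    tally["part_id"] = _part_of(geometry, parts, tally["x"].to_numpy(), tally["y"].to_numpy())
    tally = tally.drop(columns=["x", "y"]).reset_index(drop=True)

    habitat = _tally_trees(trees, cx, cy, geometry.habitat_plot_radius, 5.0)
    habitat["x_rel"] = habitat["x"] - cx
    habitat["y_rel"] = habitat["y"] - cy
    habitat = habitat.drop(columns=["x", "y"]).reset_index(drop=True)

    # small trees: two diameter classes (0-2.5 and 2.5-5 cm) on 5.3 m^2 circles
    small_rows = []
    for name, (sx, sy) in geometry.smalltree_subplot_centers().items():
        d = np.hypot(trees["x"] - sx, trees["y"] - sy)
        on = trees.loc[(d <= geometry.smalltree_subplot_radius) & (trees["dbh_cm"] < 5.0)]
        small_rows.append(
            {
                "subplot": name,
                "n_class1": int((on["dbh_cm"] < 2.5).sum()),
                "n_class2": int((on["dbh_cm"] >= 2.5).sum()),
            }
        )
    smalltrees = pd.DataFrame(small_rows)

    # regeneration: trees taller than 30 cm on the five 16 m^2 subplots
    regen_rows = []
    for name, (sx, sy) in geometry.regen_subplot_centers().items():
        d = np.hypot(trees["x"] - sx, trees["y"] - sy)
        on = trees.loc[(d <= geometry.regen_subplot_radius) & (trees["height_m"] > 0.3)]
        regen_rows.append({"subplot": name, "n_trees": int(len(on))})
    regen = pd.DataFrame(regen_rows)

    deadwood = _intersect_deadwood(landscape.deadwood, geometry)

    cover = landscape.berry_cover_at(cx, cy)
    berry = pd.DataFrame(
        [
            {"quadrat": q, "species": sp, "cover": cover.get(sp, 0.0)}
            for q in _CARDINALS
            for sp in ("bilberry", "lingonberry")
        ]
    )
    droppings = landscape.dropping_count_at(cx, cy, DROPPING_PLOT_AREA_M2)

    cols = [c for c in _TREE_COLS if c in tally.columns] + [
        c for c in tally.columns if c not in _TREE_COLS
    ]
    return PlotObservation(
        plot_id=plot_id,
        geometry=geometry,
        parts=parts,
        trees=tally[cols],
        habitat_trees=habitat,
        smalltrees=smalltrees,
        regen=regen,
        deadwood=deadwood,
        berry=berry,
        droppings=droppings,
        vegetation_type=landscape.vegetation_type_at(cx, cy),
    )


def _intersect_deadwood(pieces: pd.DataFrame, geometry: PlotGeometry) -> pd.DataFrame:
    """Downed pieces crossing the two 18 m transects.

    A piece is a straight segment (centre, azimuth, length); the diameter at
    the intersection point is interpolated linearly from root to top.
    """
    cols = ["transect_id", "species_group", "decay_class", "length_m",
            "diameter_cm", "d_root_cm", "d_cross_cm", "d_top_cm"]
    rows = []
    if len(pieces) == 0:
        return pd.DataFrame(columns=cols)
    transects = geometry.transects()
    near = pieces[
        np.hypot(pieces["x"] - geometry.center[0], pieces["y"] - geometry.center[1])
        <= geometry.transect_length_m  # cheap prefilter; max reach is L/2 + L/2
    ]
    for _, p in near.iterrows():
        az = math.radians(p["azimuth_deg"])
        hx = math.sin(az) * p["length_m"] / 2.0
        hy = math.cos(az) * p["length_m"] / 2.0
        seg = LineString([(p["x"] - hx, p["y"] - hy), (p["x"] + hx, p["y"] + hy)])
        for tid, tr in transects.items():
            inter = seg.intersection(tr)
            if inter.is_empty:
                continue
            pt = inter if inter.geom_type == "Point" else inter.representative_point()
            t = seg.project(pt) / seg.length  # 0 at root end, 1 at top
            d_at = p["d_root_cm"] + (p["d_top_cm"] - p["d_root_cm"]) * t
            rows.append(
                {
                    "transect_id": tid,
                    "species_group": p["species_group"],
                    "decay_class": p["decay_class"],
                    "length_m": p["length_m"],
                    "diameter_cm": d_at,
                    "d_root_cm": p["d_root_cm"],
                    "d_cross_cm": p.get("d_cross_cm", (p["d_root_cm"] + p["d_top_cm"]) / 2),
                    "d_top_cm": p["d_top_cm"],
                }
            )
    return pd.DataFrame(rows, columns=cols) if not rows else pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# h-tree selection (angle-count subsample for height measurement)


def angle_count_limit(dbh_cm, baf_m2ha: float) -> np.ndarray:
    """Inclusion-circle radius (m) of the relascope: dbh(m) * 50 / sqrt(BAF)."""
    return np.asarray(dbh_cm, dtype=float) * 0.5 / math.sqrt(baf_m2ha)


@dataclass
class HTreeSelection:
    selected: np.ndarray  # boolean mask over the input trees
    baf_m2ha: float | None  # None when all trees are measured (n <= 10)
    selection_prob: np.ndarray  # pi_i used for correction-factor weights
    weights: np.ndarray  # 1/pi_i

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def select_h_trees(
    dbh_cm,
    distance_m,
    prev_dbh_cm=None,
    prev_distance_m=None,
    baf_ladder=BAF_LADDER,
    max_h_trees: int = MAX_H_TREES,
    plot_radius: float | None = None,
) -> HTreeSelection:
    """Choose the height-measurement subsample of a plot's trees.

    With ``max_h_trees`` or fewer trees, all are measured (uniform weights).
    Otherwise the smallest basal-area factor in the ladder whose angle-count
    tally does not exceed ``max_h_trees`` is chosen — from the previous
    visit's dbh/distance records when available, else from the current
    calipered trees (new plots; same result, different field order) — and a
    tree is selected iff its distance is within its relascope limit.
    Selection probabilities are proportional to basal area: pi_i =
    min(1, (limit_i / plot radius)^2), the chance that a uniformly placed
    stem at that basal area falls inside its inclusion circle.
    """
    d = np.asarray(dbh_cm, dtype=float)
    r = np.asarray(distance_m, dtype=float)
    n = d.size
    R = plot_radius if plot_radius is not None else _radius(TREE_PLOT_AREA_M2)
    if n <= max_h_trees:
        return HTreeSelection(np.ones(n, bool), None, np.ones(n), np.ones(n))
    if prev_dbh_cm is None or prev_distance_m is None:
        prev_dbh_cm, prev_distance_m = d, r
    pd_, pr = np.asarray(prev_dbh_cm, float), np.asarray(prev_distance_m, float)
    baf = baf_ladder[-1]
    for cand in sorted(baf_ladder):
        if int((pr <= angle_count_limit(pd_, cand)).sum()) <= max_h_trees:
            baf = cand
            break
    limit = angle_count_limit(d, baf)
    selected = r <= limit
    prob = np.minimum(1.0, (limit / R) ** 2)
    return HTreeSelection(selected, baf, prob, 1.0 / prob)


# ---------------------------------------------------------------------------
# CHI woodland key habitats on the 0.2 ha plot


@dataclass(frozen=True)
class ChiHabitatRecord:
    habitat_type: str
    n_objects: int
    polygon_area_within_plot_m2: float


@dataclass
class ChiConfig:
    """Regional knobs of the key-habitat rules."""

    region: str = "default"  # "default" | "west_north" | "north"
    nutrient_bark_density: float = 20.0  # trees/ha; 60 in West and North Norway
    nutrient_bark_chain_m: float = 25.0  # 15 m in the stricter regional variant
    old_tree_min_age: dict = field(
        default_factory=lambda: {"spruce": 150.0, "pine": 200.0}
    )
    old_tree_min_dbh_boreal: float = 30.0
    old_tree_min_dbh_noble: float = 40.0
    luxuriant_vegetation_types: tuple = ("tall_herb", "low_herb", "meadow")

    def __post_init__(self) -> None:
        if self.region in ("west_north", "north"):
            self.nutrient_bark_density = 60.0
            self.nutrient_bark_chain_m = 15.0


_LATE_SUCC_SPECIES = {"aspen", "populus", "rowan", "sorbus", "grey_alder",
                      "alnus", "goat_willow", "salix", "bird_cherry", "prunus",
                      "birch", "betula"}
_NOBLE_HARDWOODS = {"oak", "ash", "elm", "lime", "maple", "beech", "hazel"}


def _chains(xy: np.ndarray, max_dist: float) -> list[np.ndarray]:
    """Union-find distance chaining: objects within ``max_dist`` of another
    qualifying object belong to the same patch."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= max_dist:
                parent[find(i)] = find(j)
    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    return [np.array(v) for v in roots.values()]


def _hull_area(xy: np.ndarray) -> float:
    if len(xy) < 3:
        return 0.0
    return float(MultiPoint([tuple(p) for p in xy]).convex_hull.area)


def _evaluate_density_rule(
    xy: np.ndarray, density_per_ha: float, chain_m: float | None, plot_area_ha: float
) -> tuple[bool, int, float]:
    """(qualifies, object count of best patch, patch hull area)."""
    need = density_per_ha * plot_area_ha
    if len(xy) == 0:
        return False, 0, 0.0
    groups = _chains(xy, chain_m) if chain_m is not None else [np.arange(len(xy))]
    best = max(groups, key=len)
    return len(best) >= need, len(best), _hull_area(xy[best])


def classify_chi_habitats(obs: PlotObservation, config: ChiConfig | None = None):
    """Evaluate the key-habitat rules on the 0.2 ha plot.

    Returns ``(records, not_assessed)``: habitats found, and category names
    that could not be assessed because an optional attribute (e.g. lichen
    flags) is missing from the observation bundle.
    """
    cfg = config or ChiConfig()
    trees = obs.habitat_trees
    if len(trees) == 0:
        trees = pd.DataFrame(
            columns=["species", "species_group", "dbh_cm", "age", "status",
                     "standing", "x_rel", "y_rel"]
        )
    area_ha = HABITAT_PLOT_AREA_M2 / 1e4
    records: list[ChiHabitatRecord] = []
    not_assessed: list[str] = []

    def xy(df) -> np.ndarray:
        if len(df) == 0:
            return np.empty((0, 2))
        return df[["x_rel", "y_rel"]].to_numpy(dtype=float)

    def add(name, ok, n, hull):
        if ok:
            records.append(ChiHabitatRecord(name, n, min(hull, HABITAT_PLOT_AREA_M2)))

    # standing deadwood: >= 40 standing dead trees/ha with dbh >= 10 cm,
    # chained at <= 15 m
    dead = trees[(trees["status"] == "dead") & trees["standing"] & (trees["dbh_cm"] >= 10.0)]
    add("standing_deadwood", *_evaluate_density_rule(xy(dead), 40.0, 15.0, area_ha))

    # downed deadwood: >= 40 downed pieces/ha with root-end diameter >= 10 cm
    downed = getattr(obs, "downed_on_habitat_plot", None)
    if downed is None:
        downed_trees = trees[(trees["status"] == "dead") & ~trees["standing"] & (trees["dbh_cm"] >= 10.0)]
        add("downed_deadwood", *_evaluate_density_rule(xy(downed_trees), 40.0, 15.0, area_ha))
    else:
        pts = downed[["x_rel", "y_rel"]].to_numpy(float) if len(downed) else np.empty((0, 2))
        keep = downed["d_root_cm"].to_numpy(float) >= 10.0 if len(downed) else np.empty(0, bool)
        add("downed_deadwood", *_evaluate_density_rule(pts[keep], 40.0, 15.0, area_ha))

    # nutrient-rich bark: maple or lobarion-lichen carriers
    if "has_lobarion" not in trees.columns:
        not_assessed.append("nutrient_rich_bark")
    else:
        live = trees[trees["status"] == "live"]
        rich = live[(live["species"].str.lower() == "maple") | live["has_lobarion"].fillna(False)]
        add(
            "nutrient_rich_bark",
            *_evaluate_density_rule(
                xy(rich), cfg.nutrient_bark_density, cfg.nutrient_bark_chain_m, area_ha
            ),
        )

    # pendant lichens: >= 100 carrier trees/ha (no chaining rule)
    if "has_pendant_lichens" not in trees.columns:
        not_assessed.append("pendant_lichens")
    else:
        carriers = trees[trees["has_pendant_lichens"].fillna(False)]
        add("pendant_lichens", *_evaluate_density_rule(xy(carriers), 100.0, None, area_ha))

    # late-successional deciduous: >= 40 live trees/ha, dbh >= 20 cm, of the
    # listed boreal broadleaves (northern region: aspen only)
    live = trees[trees["status"] == "live"]
    species_ok = live["species"].str.lower().isin(
        {"aspen", "populus"} if cfg.region == "north" else _LATE_SUCC_SPECIES
    )
    late = live[species_ok & (live["dbh_cm"] >= 20.0)]
    add("late_successional_deciduous", *_evaluate_density_rule(xy(late), 40.0, None, area_ha))

    # old trees: >= 30 standing old trees/ha, chained at <= 20 m
    if "age" not in trees.columns or trees["age"].isna().all() and len(trees):
        not_assessed.append("old_trees")
    else:
        standing = trees[(trees["status"] != "removed") & trees["standing"]]
        grp = standing["species"].map(species_group)
        old = np.zeros(len(standing), dtype=bool)
        for g, min_age in cfg.old_tree_min_age.items():
            old |= ((grp == g) & (standing["age"] >= min_age)).to_numpy()
        is_noble = standing["species"].str.lower().isin(_NOBLE_HARDWOODS).to_numpy()
        is_decid = (grp == "deciduous").to_numpy()
        old |= is_decid & ~is_noble & (standing["dbh_cm"] >= cfg.old_tree_min_dbh_boreal).to_numpy()
        old |= is_noble & (standing["dbh_cm"] >= cfg.old_tree_min_dbh_noble).to_numpy()
        add("old_trees", *_evaluate_density_rule(xy(standing[old]), 30.0, 20.0, area_ha))

    # luxuriant ground vegetation: nutrient-rich vegetation type
    if obs.vegetation_type is None:
        not_assessed.append("luxuriant_vegetation")
    elif obs.vegetation_type in cfg.luxuriant_vegetation_types:
        records.append(ChiHabitatRecord("luxuriant_vegetation", 0, HABITAT_PLOT_AREA_M2))

    return records, not_assessed
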