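"""Sampling design: stratified multi-resolution grids and Latin-square panels.

The design places permanent plots on a 3 km x 3 km base grid.  The country is
tessellated into 45 km x 45 km Latin squares of 5 x 5 blocks (81 km^2 each,
holding 9 plot locations); the 5 x 5 panel matrix is a Latin square and no two
edge-adjacent blocks anywhere in the tiling share a panel, so each annual
panel is spatially balanced.  Four strata thin the base grid:

========  =================  ==========================  ==================
stratum   grid (km)          membership                  weight (km^2/plot)
========  =================  ==========================  ==================
1         3 x 3              lowland, outside Finnmark   9
2         3 x 9              alpine, outside Finnmark    27
3         3 x 3              productive Finnmark         9
4         9 x 9              remaining Finnmark          81*
========  =================  ==========================  ==================

*On the idealized planar grid a 9 x 9 km lattice represents exactly 81 km^2
per plot; operational figures quote ~82 km^2 because real meridian
convergence shrinks northern grid cells.  An override table accepts official
weights for real-data use.

Alpine membership outside mapped regions is interpolated by universal
kriging of the stratum indicator with logit-transformed elevation as trend
covariate (spherical variogram; the operational fit had zero nugget, sill
0.73, range 5600 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep
from shapely.strtree import STRtree

from .raster import Raster
from .variogram import SphericalVariogram, universal_kriging

__all__ = [
    "Stratum",
    "DEFAULT_STRATA",
    "LatinSquareBlock",
    "PlotLocation",
    "StratumRules",
    "generate_grid",
    "tessellate_latin_squares",
    "block_plot_locations",
    "assign_stratum",
    "krige_stratum_probability",
    "densify_reserve_plots",
]

BASE_SPACING_M = 3000.0
BLOCK_SIZE_M = 9000.0
SQUARE_SIZE_M = 45000.0
RESERVE_OFFSET_M = 1500.0


@dataclass(frozen=True)
class Stratum:
    id: int
    spacing_km: tuple[float, float]  # (dx, dy)
    weight_km2: float  # land area represented by one plot

    def __post_init__(self) -> None:
        if self.weight_km2 <= 0:
            raise ValueError("sampling weight must be > 0")
        if any(s not in (3.0, 9.0) for s in self.spacing_km):
            raise ValueError("grid spacing must be 3 or 9 km")


#: Idealized planar weights (see module docstring for the 81-vs-82 note).
DEFAULT_STRATA: dict[int, Stratum] = {
    1: Stratum(1, (3.0, 3.0), 9.0),
    2: Stratum(2, (3.0, 9.0), 27.0),
    3: Stratum(3, (3.0, 3.0), 9.0),
    4: Stratum(4, (9.0, 9.0), 81.0),
}


@dataclass(frozen=True)
class LatinSquareBlock:
    square_index: tuple[int, int]  # (row, col) of the 45 km Latin square
    block_index: tuple[int, int]  # (i, j) in 0..4 x 0..4 within the square
    panel: int  # 1..5, the year within the 5-year cycle
    extent: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)

    @property
    def area_km2(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin) / 1e6


@dataclass
class PlotLocation:
    id: int
    x: float
    y: float
    stratum: int | None  # None = outside the sampled population
    panel: int
    is_reserve_extra: bool = False


def generate_grid(extent, spacing, origin=(0.0, 0.0)) -> np.ndarray:
    """All lattice nodes ``origin + k*spacing`` inside ``extent``.

    Inclusion is half-open: west/south edges included, east/north excluded.
    Nodes are returned row-major (south to north, west to east within row),
    shape ``(n, 2)``.
    """
    xmin, ymin, xmax, ymax = extent
    dx, dy = (spacing, spacing) if np.isscalar(spacing) else spacing
    if dx <= 0 or dy <= 0:
        raise ValueError("spacing must be > 0")
    if xmax <= xmin or ymax <= ymin:
        return np.empty((0, 2))
    ox, oy = origin
    kx0 = int(np.ceil((xmin - ox) / dx))
    kx1 = int(np.ceil((xmax - ox) / dx))  # exclusive
    ky0 = int(np.ceil((ymin - oy) / dy))
    ky1 = int(np.ceil((ymax - oy) / dy))
    xs = ox + dx * np.arange(kx0, kx1)
    ys = oy + dy * np.arange(ky0, ky1)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def panel_of_block(i: int, j: int) -> int:
    """Cyclic Latin-square panel for block row i, column j (0-based).

    ``(i + 2j) mod 5 + 1`` is a Latin square (2 is coprime to 5) and, because
    row-neighbours differ by 1 and column-neighbours by 2 (mod 5), no two
    edge-adjacent blocks share a panel even across square boundaries of the
    repeating 45 km tiling.
    """
    return (i + 2 * j) % 5 + 1


def tessellate_latin_squares(extent, origin=(0.0, 0.0)) -> list[LatinSquareBlock]:
    """Tile ``extent`` with 45 km Latin squares of 25 blocks (81 km^2 each).

    A block is returned iff its south-west corner lies inside ``extent``
    (half-open, consistent with :func:`generate_grid`).
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent must be non-degenerate")
    corners = generate_grid(extent, BLOCK_SIZE_M, origin)
    blocks = []
    ox, oy = origin
    for bx, by in corners:
        gi = round((by - oy) / BLOCK_SIZE_M)  # global block row (south->north)
        gj = round((bx - ox) / BLOCK_SIZE_M)
        sq = (gi // 5, gj // 5)
        i, j = gi % 5, gj % 5
        blocks.append(
            LatinSquareBlock(
                square_index=sq,
                block_index=(i, j),
                panel=panel_of_block(i, j),
                extent=(bx, by, bx + BLOCK_SIZE_M, by + BLOCK_SIZE_M),
            )
        )
    return blocks


def block_plot_locations(block: LatinSquareBlock) -> np.ndarray:
    """The 9 base-grid plot locations of a block (3 km lattice, 1.5 km inset)."""
    xmin, ymin, _, _ = block.extent
    return generate_grid(
        block.extent, BASE_SPACING_M, (xmin + 1500.0, ymin + 1500.0)
    )


@dataclass
class StratumRules:
    """Stratum membership configuration.

    ``alpine_threshold_m`` may vary regionally (operationally 100–800 m
    a.s.l. along the coast and in the north); a scalar applies everywhere.
    ``finnmark_region`` is a shapely polygon (None = no Finnmark analogue in
    the landscape).  ``productive_finnmark`` is a polygon of the productive
    (stratum 3) part of Finnmark.  ``subgrid_phase`` selects which base-grid
    rows/columns belong to the coarser stratum-2/4 lattices.
    """

    alpine_threshold_m: float = 500.0
    finnmark_region: object | None = None
    productive_finnmark: object | None = None
    subgrid_phase: tuple[int, int] = (0, 0)
    grid_origin: tuple[float, float] = (0.0, 0.0)


def _on_sublattice(x, y, rules: StratumRules, every_x: int, every_y: int) -> bool:
    ox, oy = rules.grid_origin
    px, py = rules.subgrid_phase
    ix = round((x - ox) / BASE_SPACING_M)
    iy = round((y - oy) / BASE_SPACING_M)
    return (every_x == 1 or ix % every_x == px % every_x) and (
        every_y == 1 or iy % every_y == py % every_y
    )


def assign_stratum(location, elevation: Raster, rules: StratumRules) -> int | None:
    """Stratum id for a base-grid plot location, or None if unsampled.

    Outside Finnmark: stratum 1 below the alpine threshold; above it the
    location belongs to stratum 2 and is retained in the sample only if it
    falls on the 3 km x 9 km sub-lattice.  Inside Finnmark: stratum 3 within
    the productive region (3 km grid), else stratum 4 retained only on the
    9 km x 9 km sub-lattice.
    """
    x, y = float(location[0]), float(location[1])
    xmin, ymin, xmax, ymax = elevation.extent
    if not (xmin <= x < xmax and ymin <= y < ymax):
        return None
    in_finnmark = rules.finnmark_region is not None and rules.finnmark_region.covers(
        Point(x, y)
    )
    if in_finnmark:
        if rules.productive_finnmark is not None and rules.productive_finnmark.covers(
            Point(x, y)
        ):
            return 3
        return 4 if _on_sublattice(x, y, rules, 3, 3) else None
    if float(elevation.sample(x, y)) < rules.alpine_threshold_m:
        return 1
    return 2 if _on_sublattice(x, y, rules, 1, 3) else None


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def krige_stratum_probability(
    obs_points,
    obs_indicator,
    covariate: Raster,
    model: SphericalVariogram,
    elevation_scale: float = 1500.0,
) -> tuple[Raster, Raster]:
    """Universal kriging of a stratum indicator to a probability map.

    The trend covariate is the logit of elevation rescaled to (0, 1) by
    ``elevation_scale``.  Returns ``(probability, stratum_map)``: the kriged
    surface clipped to [0, 1] and its 0.5-threshold indicator raster on the
    covariate grid.  With a zero-nugget model the surface interpolates the
    indicator exactly at the observed nodes.
    """
    obs_points = np.asarray(obs_points, dtype=float)
    obs_ind = np.asarray(obs_indicator, dtype=float)
    cov_obs = _logit(np.asarray(covariate.sample(obs_points[:, 0], obs_points[:, 1])) / elevation_scale)
    xs, ys = covariate.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    pred_pts = np.column_stack([gx.ravel(), gy.ravel()])
    cov_pred = _logit(covariate.data.ravel() / elevation_scale)
    z = universal_kriging(obs_points, obs_ind, cov_obs, pred_pts, cov_pred, model)
    prob = np.clip(z, 0.0, 1.0).reshape(covariate.data.shape)
    prob_r = Raster(prob, covariate.x0, covariate.y0, covariate.cell_size)
    strat_r = Raster((prob >= 0.5).astype(float), covariate.x0, covariate.y0, covariate.cell_size)
    return prob_r, strat_r


def densify_reserve_plots(locations, reserve_polygons) -> list[PlotLocation]:
    """Extra plots 1.5 km north and east of base plots, kept iff in a reserve.

    ``locations`` is a sequence of :class:`PlotLocation`; candidates inherit
    stratum and panel from their base plot and are flagged
    ``is_reserve_extra``.
    """
    if not reserve_polygons:
        return []
    tree = STRtree(list(reserve_polygons))
    prepared = [prep(g) for g in reserve_polygons]
    out: list[PlotLocation] = []
    next_id = max((loc.id for loc in locations), default=-1) + 1
    for loc in locations:
        for dx, dy in ((0.0, RESERVE_OFFSET_M), (RESERVE_OFFSET_M, 0.0)):
            cand = Point(loc.x + dx, loc.y + dy)
            hit = any(prepared[i].covers(cand) for i in tree.query(cand))
            if hit:
                out.append(
                    PlotLocation(
                        id=next_id,
                        x=cand.x,
                        y=cand.y,
                        stratum=loc.stratum,
                        panel=loc.panel,
                        is_reserve_extra=True,
                    )
                )
                next_id += 1
    return out
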