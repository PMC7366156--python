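"""Design-based and synthetic estimators for the plot network.

Stratified expansion: each plot represents ``w_h`` km^2 of land; totals of a
per-hectare plot value y are Sum_h w_h * 100 * Sum_{i in h} y_i (the factor
100 converts km^2 to ha).  Variances deliberately assume simple random
sampling within strata, without finite-population correction — conservative
for the systematic grid actually used.

Downed-deadwood volume per plot comes from line intersect sampling on the
two 18 m transects: v (m^3/ha) = pi^2 / (8 L) * Sum d_i^2 * 1e4 with the
intersection diameters d_i in metres and the transect length L in metres.

Small-area harvest estimates aggregate a volume raster over change-mask
cells per region, scaled by the utilized fraction of standing volume
(default 0.8; the rest is assumed left in the forest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.prepared import prep

from .raster import Raster
from .sampling import DEFAULT_STRATA

__all__ = [
    "EstimationResult",
    "StratumFrame",
    "expand_total",
    "proportion_with_se",
    "lis_plot_volume",
    "lis_deadwood_volume",
    "synthetic_harvest_estimate",
]


@dataclass(frozen=True)
class EstimationResult:
    domain: str
    estimate: float
    se: float
    n_plots: int
    estimator: str  # expansion | ratio | lis | synthetic
    units: str = ""

    def __post_init__(self) -> None:
        if self.se < 0 or self.n_plots < 0:
            raise ValueError("se and n_plots must be non-negative")


@dataclass
class StratumFrame:
    """Plot values organized by stratum for expansion estimation.

    ``values`` maps stratum id -> per-plot values (per-ha units; 0 for
    plots outside the domain).  ``weights_km2`` defaults to the design
    weights; ``areas_km2`` optionally supplies official stratum land areas
    (otherwise n_h * w_h is used, the self-consistent expansion).
    """

    values: dict[int, np.ndarray]
    weights_km2: dict[int, float] = field(
        default_factory=lambda: {k: s.weight_km2 for k, s in DEFAULT_STRATA.items()}
    )
    areas_km2: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.values = {h: np.asarray(v, dtype=float) for h, v in self.values.items()}
        for h in self.values:
            if self.weights_km2.get(h, 0) <= 0:
                raise ValueError(f"stratum {h} needs a positive sampling weight")

    def area_km2(self, h: int) -> float:
        if self.areas_km2 and h in self.areas_km2:
            return self.areas_km2[h]
        return len(self.values[h]) * self.weights_km2[h]


def _collapse_singletons(frame: StratumFrame) -> dict[int, np.ndarray]:
    """Merge single-plot strata into the nearest (by id) neighbour stratum
    for variance estimation only, as the documented conservative rule."""
    values = {h: v for h, v in frame.values.items() if len(v) > 0}
    single = [h for h, v in values.items() if len(v) == 1]
    multi = [h for h, v in values.items() if len(v) > 1]
    if not single or not multi:
        return values
    out = {h: v.copy() for h, v in values.items() if h in multi}
    for h in single:
        tgt = min(multi, key=lambda m: abs(m - h))
        warnings.warn(f"stratum {h} has one plot; collapsed with stratum {tgt} for SE")
        out[tgt] = np.concatenate([out[tgt], values[h]])
    return out


def expand_total(frame: StratumFrame, domain: str = "all", units: str = "") -> EstimationResult:
    """Stratified expansion estimate of a population total.

    Plot values are per-ha quantities (an indicator for area estimation);
    the result is in [value units] * ha.  SE assumes SRS within strata.
    """
    total = 0.0
    n = 0
    for h, y in frame.values.items():
        total += frame.weights_km2[h] * 100.0 * float(np.sum(y))
        n += len(y)
    var = 0.0
    for h, y in _collapse_singletons(frame).items():
        nh = len(y)
        w = frame.weights_km2[h] * 100.0
        # Var(w * n_h * ybar) = (w n_h)^2 s^2 / n_h, no fpc
        var += (w * nh) ** 2 * np.var(y, ddof=1) / nh
    return EstimationResult(domain, total, float(np.sqrt(var)), n, "expansion", units)


def proportion_with_se(frame: StratumFrame, domain: str = "all") -> EstimationResult:
    """Stratified proportion with SRS variance p(1-p)/(n-1) per stratum,
    combined by stratum area shares."""
    total_area = sum(frame.area_km2(h) for h in frame.values)
    if total_area <= 0 or all(len(v) == 0 for v in frame.values.values()):
        raise ValueError("cannot estimate a proportion from an empty frame")
    p = 0.0
    var = 0.0
    n = 0
    for h, y in frame.values.items():
        if len(y) == 0:
            continue
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("proportion estimation needs 0/1 indicators")
        a = frame.area_km2(h) / total_area
        ph = float(np.mean(y))
        p += a * ph
        n += len(y)
        if len(y) > 1:
            var += a**2 * ph * (1 - ph) / (len(y) - 1)
    return EstimationResult(domain, p, float(np.sqrt(var)), n, "expansion", "proportion")


def lis_plot_volume(intersection_diameters_cm, transect_length_m: float = 36.0) -> float:
    """Per-plot downed-deadwood volume (m^3/ha) by line intersect sampling.

    ``transect_length_m`` is the recorded total length (2 x 18 m unless
    truncated at plot-part boundaries).
    """
    if transect_length_m <= 0:
        raise ValueError("transect length must be > 0 (plot excluded)")
    d_m = np.asarray(intersection_diameters_cm, dtype=float) / 100.0
    return float(np.pi**2 / (8.0 * transect_length_m) * np.sum(d_m**2) * 1e4)


def lis_deadwood_volume(
    per_plot_diameters: dict[int, list],
    frame_values_template: StratumFrame | None = None,
    transect_lengths: dict | None = None,
    strata_of_plots: dict | None = None,
    weights_km2: dict[int, float] | None = None,
) -> tuple[pd.Series, EstimationResult | None]:
    """Plot-level LIS volumes, optionally expanded to a population total.

    ``per_plot_diameters`` maps plot id -> intersection diameters (cm);
    ``strata_of_plots`` maps plot id -> stratum for expansion (omit for
    plot-level output only).  Zero-length transects are excluded with a
    warning.
    """
    vals = {}
    for pid, diams in per_plot_diameters.items():
        L = (transect_lengths or {}).get(pid, 36.0)
        if L <= 0:
            warnings.warn(f"plot {pid} has zero transect length; excluded")
            continue
        vals[pid] = lis_plot_volume(diams, L)
    series = pd.Series(vals, dtype=float)
    if strata_of_plots is None:
        return series, None
    by_stratum: dict[int, list] = {}
    for pid, v in series.items():
        by_stratum.setdefault(strata_of_plots[pid], []).append(v)
    frame = StratumFrame(
        {h: np.array(v) for h, v in by_stratum.items()},
        weights_km2=weights_km2 or {k: s.weight_km2 for k, s in DEFAULT_STRATA.items()},
    )
    return series, expand_total(frame, "deadwood", "m3")


def synthetic_harvest_estimate(
    volume_raster: Raster,
    change_mask: Raster,
    region_polygons: dict,
    utilization: float = 0.8,
) -> tuple[dict, Raster]:
    """Per-region harvested volume from a volume map and a change mask.

    harvest(region) = utilization * Sum over changed cells in the region of
    volume_per_ha * cell_area_ha.  Returns the estimates and the updated
    volume raster with changed cells set to zero.
    """
    if (volume_raster.data.shape != change_mask.data.shape
            or volume_raster.x0 != change_mask.x0
            or volume_raster.y0 != change_mask.y0
            or volume_raster.cell_size != change_mask.cell_size):
        raise ValueError("volume raster and change mask are not co-registered")
    xs, ys = volume_raster.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    changed = change_mask.data > 0
    cell_ha = volume_raster.cell_area_ha
    out = {}
    from shapely.geometry import Point

    for name, poly in region_polygons.items():
        pp = prep(poly)
        m = changed & np.fromiter(
            (pp.covers(Point(x, y)) for x, y in zip(gx.ravel(), gy.ravel())),
            dtype=bool, count=gx.size,
        ).reshape(gx.shape)
        out[name] = utilization * float(np.nansum(volume_raster.data[m])) * cell_ha
    updated = Raster(
        np.where(changed, 0.0, volume_raster.data),
        volume_raster.x0, volume_raster.y0, volume_raster.cell_size,
    )
    return out, updated
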