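"""Tree-level prediction chain and stand-level classifiers.

Every tallied tree gets a volume.  Heights are measured only on a subsample
(h-trees); all other trees get a model-approximated height, a volume from
(dbh, approximated height), and a plot- and species-group-level *correction
factor* — the ratio of volume sums computed with measured versus approximated
heights over the h-trees, each tree inversely weighted by its angle-count
selection probability so that small trees (rarely selected) carry more
weight.  Final heights of non-h-trees are recovered by solving the volume
function for height.

The published Norwegian/Swedish coefficient sets are proprietary to their
sources and are not shipped; the module provides documented stand-in
coefficients of the same functional families, loadable from YAML so real
sets can be dropped in.  Everything downstream (correction factors, back
solving, increment) is allometry-agnostic.

Function families
-----------------
height (Näslund, power 3):   h = 1.3 + (d / (a + b d))^3         [d cm, h m]
volume (power law):          v = a d^b h^c                       [v m^3]
biomass (log-ratio):         B = exp(c0 + c1 d/(d + k))          [B kg]
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SPECIES_GROUPS",
    "AllometrySet",
    "DEFAULT_COEFFICIENTS",
    "species_group",
    "volume_function_key",
    "CorrectionContext",
    "plot_correction_factors",
    "predict_tree_volume",
    "predict_biomass",
    "SeasonCalendar",
    "growing_seasons",
    "annual_volume_increment",
    "impute_annual_dbh_difference",
    "removal_volume",
    "site_index_class",
    "stand_age",
    "MaturityThresholds",
    "maturity_class",
]

#: Tally groups used for correction factors and species-mix reporting.
SPECIES_GROUPS = ("spruce", "pine", "deciduous")

_SPRUCE_FIR = {"spruce", "norway_spruce", "fir", "silver_fir", "subalpine_fir"}
_SITKA = {"sitka", "sitka_spruce"}
_OTHER_CONIFERS = {"pine", "scots_pine", "lodgepole_pine", "larch", "juniper", "yew"}


def species_group(species_code: str) -> str:
    """Tally group (spruce / pine / deciduous) for a species code."""
    s = species_code.lower()
    if s in _SPRUCE_FIR or s in _SITKA:
        return "spruce"
    if s in _OTHER_CONIFERS:
        return "pine"
    return "deciduous"


def volume_function_key(species_code: str) -> str:
    """Which function set predicts this species.

    Spruce and fir species share the spruce functions except Sitka spruce,
    which has its own set; all other conifers use the pine functions; all
    broadleaves use the deciduous (birch) functions.
    """
    s = species_code.lower()
    if s in _SITKA:
        return "sitka"
    if s in _SPRUCE_FIR:
        return "spruce"
    if s in _OTHER_CONIFERS:
        return "pine"
    return "deciduous"


#: Stand-in coefficient sets (same functional families as the operational
#: chain; see module docstring).  Asymptotic heights 1.3 + b^-3.
DEFAULT_COEFFICIENTS: dict[str, dict] = {
    "spruce": {
        "height": {"form": "naslund3", "a": 2.3, "b": 0.32},
        "volume": {"form": "power_dh", "a": 4.0e-5, "b": 1.8, "c": 1.1},
        "biomass_ag": {"form": "log_ratio", "c0": -2.0, "c1": 11.0, "k": 12.0},
        "biomass_bg": {"form": "log_ratio", "c0": -3.2, "c1": 10.5, "k": 14.0},
    },
    "sitka": {
        "height": {"form": "naslund3", "a": 2.2, "b": 0.31},
        "volume": {"form": "power_dh", "a": 4.1e-5, "b": 1.8, "c": 1.1},
        "biomass_ag": {"form": "log_ratio", "c0": -2.0, "c1": 11.1, "k": 12.0},
        "biomass_bg": {"form": "log_ratio", "c0": -3.2, "c1": 10.6, "k": 14.0},
    },
    "pine": {
        "height": {"form": "naslund3", "a": 2.6, "b": 0.34},
        "volume": {"form": "power_dh", "a": 3.7e-5, "b": 1.82, "c": 1.08},
        "biomass_ag": {"form": "log_ratio", "c0": -2.2, "c1": 11.2, "k": 13.0},
        "biomass_bg": {"form": "log_ratio", "c0": -3.4, "c1": 10.8, "k": 15.0},
    },
    "deciduous": {
        "height": {"form": "naslund3", "a": 3.0, "b": 0.38},
        "volume": {"form": "power_dh", "a": 4.4e-5, "b": 1.78, "c": 1.05},
        "biomass_ag": {"form": "log_ratio", "c0": -2.1, "c1": 10.6, "k": 11.0},
        "biomass_bg": {"form": "log_ratio", "c0": -3.3, "c1": 10.2, "k": 13.0},
    },
}


class AllometrySet:
    """Per-species-group allometric functions with height back-solving."""

    def __init__(self, coefficients: dict[str, dict] | None = None) -> None:
        self.coefficients = coefficients or DEFAULT_COEFFICIENTS
        for key, sets in self.coefficients.items():
            vol = sets.get("volume")
            if vol is None:
                raise ValueError(f"no volume function for {key!r}")
            if vol["form"] == "power_dh" and vol["c"] <= 0:
                raise ValueError(
                    f"volume for {key!r} must be strictly increasing in height"
                )

    @classmethod
    def from_yaml(cls, path) -> "AllometrySet":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def _set(self, species: str) -> dict:
        key = volume_function_key(species)
        try:
            return self.coefficients[key]
        except KeyError:
            raise KeyError(f"no coefficients for species group {key!r}") from None

    def height(self, species: str, dbh_cm):
        """Approximate height (m) from dbh via the h-dbh function."""
        c = self._set(species)["height"]
        if c["form"] != "naslund3":
            raise ValueError(f"unknown height form {c['form']!r}")
        d = np.asarray(dbh_cm, dtype=float)
        return 1.3 + (d / (c["a"] + c["b"] * d)) ** 3

    def volume(self, species: str, dbh_cm, height_m):
        """Stem volume (m^3) from dbh (cm) and height (m)."""
        c = self._set(species)["volume"]
        if c["form"] != "power_dh":
            raise ValueError(f"unknown volume form {c['form']!r}")
        d = np.asarray(dbh_cm, dtype=float)
        h = np.asarray(height_m, dtype=float)
        return c["a"] * d ** c["b"] * h ** c["c"]

    def height_from_volume(
        self, species: str, dbh_cm: float, volume_m3: float, vol_tol: float = 1e-9
    ) -> float:
        """Solve v(dbh, h) = volume for h (unique: v strictly increasing in h)."""
        lo, hi = 0.1, 60.0
        f = lambda h: self.volume(species, dbh_cm, h) - volume_m3
        while f(hi) < 0 and hi < 1e4:
            hi *= 2
        if f(lo) > 0:
            lo = 1e-6
        if f(lo) > 0 or f(hi) < 0:
            raise RuntimeError("height back-solve failed to bracket the root")
        h = brentq(f, lo, hi, xtol=1e-10, rtol=1e-14)
        if abs(f(h)) > max(vol_tol, 1e-6):
            raise RuntimeError("height back-solve did not converge")
        return float(h)

    def biomass(self, species: str, dbh_cm):
        """(above-ground, below-ground) biomass in kg."""
        s = self._set(species)
        out = []
        for part in ("biomass_ag", "biomass_bg"):
            c = s[part]
            if c["form"] != "log_ratio":
                raise ValueError(f"unknown biomass form {c['form']!r}")
            d = np.asarray(dbh_cm, dtype=float)
            out.append(np.exp(c["c0"] + c["c1"] * d / (d + c["k"])))
        return out[0], out[1]


# ---------------------------------------------------------------------------
# correction factors and the volume chain


@dataclass(frozen=True)
class CorrectionContext:
    """Plot/species-group height-correction factor for volume prediction."""

    plot_id: object
    species_group: str
    factor: float
    source: str  # "plot" | "fallback"
    fallback_key: tuple | None = None

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("correction factor must be > 0")


def plot_correction_factors(
    plot_id,
    species_groups,
    dbh_cm,
    measured_heights,
    weights,
    allometry: AllometrySet,
    species_codes=None,
) -> dict[str, CorrectionContext]:
    """Correction factors per species group from the h-trees of one plot.

    factor = sum_i w_i v(d_i, h_i^meas) / sum_i w_i v(d_i, h_i^approx) with
    w_i = 1/pi_i, pi_i the angle-count selection probability (weights of 1
    when all trees were measured).  Species with no h-tree are absent from
    the result; the caller falls back to regional average factors.
    """
    groups = np.asarray(species_groups)
    d = np.asarray(dbh_cm, dtype=float)
    hm = np.asarray(measured_heights, dtype=float)
    w = np.asarray(weights, dtype=float)
    codes = np.asarray(species_codes) if species_codes is not None else groups
    out: dict[str, CorrectionContext] = {}
    for g in np.unique(groups):
        m = groups == g
        num = den = 0.0
        for code, di, hi, wi in zip(codes[m], d[m], hm[m], w[m]):
            ha = float(allometry.height(code, di))
            num += wi * float(allometry.volume(code, di, hi))
            den += wi * float(allometry.volume(code, di, ha))
        out[str(g)] = CorrectionContext(plot_id, str(g), num / den, "plot")
    return out


def broken_top_fraction(relative_break_height: float) -> float:
    """Fraction of stem volume lost above a break at relative height r.

    Stand-in rule: the stem above breast height is treated as a cone, so the
    part above relative height r holds (1 - r)^3 of the volume.  Only breaks
    where the stem diameter at the break is >= 10 cm are adjusted (the caller
    enforces the diameter condition).
    """
    r = float(np.clip(relative_break_height, 0.0, 1.0))
    return (1.0 - r) ** 3


def predict_tree_volume(
    species: str,
    dbh_cm: float,
    allometry: AllometrySet,
    measured_height_m: float | None = None,
    correction: CorrectionContext | float = 1.0,
    relative_break_height: float | None = None,
    apply_breakage: bool = True,
) -> tuple[float, float]:
    """(volume m^3, final height m) for one tree.

    h-trees use (dbh, measured height) directly.  Other trees use the
    approximated height, volume multiplied by the correction factor, and the
    final height is recovered by solving the volume function for height.
    Broken stems lose the cone-top fraction (correction applied first).
    """
    if dbh_cm < 5.0:
        raise ValueError("volume chain applies to trees with dbh >= 5 cm")
    factor = correction.factor if isinstance(correction, CorrectionContext) else float(correction)
    if measured_height_m is not None:
        v = float(allometry.volume(species, dbh_cm, measured_height_m))
        h = float(measured_height_m)
    else:
        h_approx = float(allometry.height(species, dbh_cm))
        v = factor * float(allometry.volume(species, dbh_cm, h_approx))
        h = allometry.height_from_volume(species, dbh_cm, v)
    if apply_breakage and relative_break_height is not None:
        v *= 1.0 - broken_top_fraction(relative_break_height)
    return v, h


def predict_biomass(species: str, dbh_cm, allometry: AllometrySet):
    """(above-ground, below-ground) biomass in kg; routed per species."""
    if np.any(np.asarray(dbh_cm, dtype=float) < 5.0):
        raise ValueError("biomass chain applies to trees with dbh >= 5 cm")
    return allometry.biomass(species, dbh_cm)


# ---------------------------------------------------------------------------
# increment, mortality, harvest


@dataclass(frozen=True)
class SeasonCalendar:
    """Growing season window: start day-of-year and length in days."""

    season_start: int = 152  # June 1 in non-leap years
    season_length: int = 100

    def __post_init__(self) -> None:
        if not 1 <= self.season_start <= 265:
            raise ValueError("season start must lie in day-of-year 1..265")

    def season_days_elapsed(self, date: _dt.date) -> float:
        # anchor the window to the calendar date of the start day (leap years
        # would otherwise shift the window by one day against the calendar)
        anchor = _dt.date(2001, 1, 1) + _dt.timedelta(days=self.season_start - 1)
        start = _dt.date(date.year, anchor.month, anchor.day)
        return float(np.clip((date - start).days, 0, self.season_length))


def growing_seasons(
    date_prev: _dt.date, date_curr: _dt.date, calendar: SeasonCalendar | None = None
) -> float:
    """Number of growing seasons between two measurement dates.

    Whole calendar years elapsed plus the difference of within-season day
    counts divided by the season length; over a 5-calendar-year cycle with a
    100-day season this ranges from 4.00 to 6.00.
    """
    if date_prev >= date_curr:
        raise ValueError("previous date must precede current date")
    cal = calendar or SeasonCalendar()
    years = date_curr.year - date_prev.year
    ds = cal.season_days_elapsed(date_curr) - cal.season_days_elapsed(date_prev)
    return years + ds / cal.season_length


def annual_volume_increment(
    species: str,
    dbh_prev_cm: float,
    dbh_curr_cm: float,
    v_curr_m3: float,
    seasons: float,
    allometry: AllometrySet,
    correction_prev: CorrectionContext | float = 1.0,
) -> float:
    """Annual stem-volume increment from repeated dbh measurements.

    The dbh one year before current is dbh_curr - (dbh_curr - dbh_prev) /
    seasons; its volume is predicted with the *previous* cycle's
    diameter-height relationship (approximated height times the previous
    correction factor); the increment is the difference to the current
    volume.
    """
    if seasons <= 0:
        raise ValueError("seasons must be > 0")
    factor = (
        correction_prev.factor
        if isinstance(correction_prev, CorrectionContext)
        else float(correction_prev)
    )
    dbh_m1 = dbh_curr_cm - (dbh_curr_cm - dbh_prev_cm) / seasons
    h_m1 = float(allometry.height(species, dbh_m1))
    v_m1 = factor * float(allometry.volume(species, dbh_m1, h_m1))
    return v_curr_m3 - v_m1


def impute_annual_dbh_difference(
    matched_trees,
    species: str,
    dbh_cm: float,
    maturity_cls: int,
    si_class: int,
    diameter_class_width: float = 5.0,
) -> float:
    """Mean annual dbh difference for ingrowth / new-plot trees.

    ``matched_trees`` is a DataFrame with columns species, dbh_cm,
    annual_dbh_diff, maturity_class, si_class of trees with repeated
    measurements.  The imputation cell is (species, 5-cm diameter class,
    maturity group {1-3 | 4-5}, site index class); empty cells widen
    hierarchically: drop site index, then the maturity group, then fall back
    to the species mean.
    """
    df = matched_trees
    dclass = int(dbh_cm // diameter_class_width)
    mgroup = 1 if maturity_cls <= 3 else 2
    t_dclass = (df["dbh_cm"] // diameter_class_width).astype(int)
    t_mgroup = np.where(df["maturity_class"] <= 3, 1, 2)
    masks = [
        (df["species"] == species)
        & (t_dclass == dclass)
        & (t_mgroup == mgroup)
        & (df["si_class"] == si_class),
        (df["species"] == species) & (t_dclass == dclass) & (t_mgroup == mgroup),
        (df["species"] == species) & (t_dclass == dclass),
        (df["species"] == species),
    ]
    for m in masks:
        if m.any():
            return float(df.loc[m, "annual_dbh_diff"].mean())
    raise ValueError(f"no matched trees to impute increment for {species!r}")


def removal_volume(v_prev_m3: float, increment_prev_annual_m3: float) -> float:
    """Volume of a removed tree: previous volume plus 2.5 years of the
    previous annual increment (the expected unobserved growth when harvests
    fall uniformly within the 5-year cycle)."""
    return v_prev_m3 + 2.5 * increment_prev_annual_m3


# ---------------------------------------------------------------------------
# stand-level classifiers


@dataclass
class StandAttributes:
    """Stand descriptors recorded on the 0.1 ha stand plot."""

    site_index_class: int = 14
    stand_age: float = 60.0
    maturity_class: int = 3
    stocking_flag: str = "sufficiently"
    dominant_species: str = "spruce"
    land_use: str = "forest"
    soil_type: str = "mineral"
    drainage_status: str = "undrained"

    def __post_init__(self) -> None:
        if self.site_index_class < 6:
            raise ValueError("site index class must be >= 6")
        if not 1 <= self.maturity_class <= 5:
            raise ValueError("maturity class must be 1..5")


H40_CLASSES = (6, 8, 11, 14, 17, 20, 23, 26)


def site_index_class(dominant_height_at_base_age_m: float, ladder=H40_CLASSES) -> int:
    """H40 site index class from dominant height at 40 years breast-height age.

    Classes are 3 m bins centred on the class values with lower-inclusive
    edges (class 14 covers [12.5, 15.5) m); ends are clamped.
    """
    if dominant_height_at_base_age_m <= 0:
        raise ValueError("dominant height must be > 0")
    ladder = np.asarray(sorted(ladder))
    bounds = (ladder[:-1] + ladder[1:]) / 2.0
    return int(ladder[np.searchsorted(bounds, dominant_height_at_base_age_m, side="right")])


def stand_age(ages, dbh_cm, layers=None) -> float:
    """Basal-area weighted mean biological age of a stand.

    In two-layered stands only the overstory contributes; one- or
    many-layered stands use all trees.  ``layers`` may be None or an array of
    labels with "overstory" marking the upper layer.
    """
    ages = np.asarray(ages, dtype=float)
    d = np.asarray(dbh_cm, dtype=float)
    if layers is not None:
        layers = np.asarray(layers)
        if len(np.unique(layers)) == 2:
            m = layers == "overstory"
            ages, d = ages[m], d[m]
    if ages.size == 0:
        raise ValueError("no aged trees in the relevant layer")
    g = np.pi / 4.0 * d**2
    return float(np.sum(g * ages) / np.sum(g))


class MaturityThresholds:
    """Entry-age table for maturity classes 3-5 by site index.

    Highly productive stands enter older classes at younger ages, so entry
    ages decrease linearly in site index between the printed extremes:

    =======  ================  =================
    class    entry at SI 6     entry at SI 26
    =======  ================  =================
    3        84                15
    4        119               25
    5        120               40
    =======  ================  =================

    The table is audited at construction: entries must be non-increasing in
    SI, ordered across classes, and lie inside the printed national ranges
    (class 3 in [15, 85), class 4 in [25, 120), class 5 in [40, 120]).
    """

    RANGES = {3: (15, 84), 4: (25, 119), 5: (40, 120)}
    SI_MIN, SI_MAX = 6, 26

    def __init__(self, ranges: dict[int, tuple[int, int]] | None = None) -> None:
        self.ranges = ranges or self.RANGES
        self._audit()

    def entry_age(self, cls: int, si_class: int) -> int:
        lo, hi = self.ranges[cls]
        si = float(np.clip(si_class, self.SI_MIN, self.SI_MAX))
        frac = (si - self.SI_MIN) / (self.SI_MAX - self.SI_MIN)
        return int(round(hi - (hi - lo) * frac))

    def _audit(self) -> None:
        sis = list(range(self.SI_MIN, self.SI_MAX + 1))
        for cls, (lo, hi) in self.ranges.items():
            entries = [self.entry_age(cls, si) for si in sis]
            if any(a < b for a, b in zip(entries, entries[1:])):
                raise ValueError(f"class {cls} entry ages must not increase with SI")
            if min(entries) < lo or max(entries) > hi:
                raise ValueError(f"class {cls} entry ages leave [{lo}, {hi}]")
        for si in sis:
            seq = [self.entry_age(c, si) for c in sorted(self.ranges)]
            if any(a > b for a, b in zip(seq, seq[1:])):
                raise ValueError(f"entry ages not ordered across classes at SI {si}")


def maturity_class(
    stand_age_yrs: float,
    si_class: int,
    crop_trees_per_ha: float | None = None,
    basal_area_m2ha: float | None = None,
    thresholds: MaturityThresholds | None = None,
    min_crop_trees_per_ha: float = 150.0,
    min_basal_area_m2ha: float = 4.0,
) -> tuple[int, str]:
    """(maturity class 1-5, stocking flag) for a productive stand.

    Age 0 is class 1 (regeneration); class 2 starts at age 1; classes 3-5
    start at the site-index-dependent entry ages of ``thresholds``.  Stocking
    is judged by potential crop trees in class 2 and basal area in classes
    3-5.
    """
    thresholds = thresholds or MaturityThresholds()
    if stand_age_yrs < 1:
        return 1, "sufficiently"
    cls = 2
    for c in (3, 4, 5):
        if stand_age_yrs >= thresholds.entry_age(c, si_class):
            cls = c
    if cls == 2:
        ok = crop_trees_per_ha is None or crop_trees_per_ha >= min_crop_trees_per_ha
    else:
        ok = basal_area_m2ha is None or basal_area_m2ha >= min_basal_area_m2ha
    return cls, "sufficiently" if ok else "poorly"
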