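"""File formats, configuration, and the end-to-end pipeline.

Everything on disk is plain text: CSV tables, GeoJSON geometries, ESRI
ASCII grids for rasters, YAML configuration, and a JSON run manifest that
records seeds and content hashes so a rerun with the same configuration is
bit-identical and an interrupted run resumes from the last completed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from . import dendrometry as dm
from . import estimation as est
from . import plots as pp
from . import sampling as sd
from .landscape import Landscape, LandscapeConfig, simulate_landscape
from .raster import Raster
from .variogram import SphericalVariogram

__all__ = [
    "write_landscape", "read_landscape_tables", "bundle_tables",
    "write_plot_tables", "read_plot_tables", "roundtrip_plot_tables",
    "RunConfig", "run_pipeline",
]

log = logging.getLogger("nfisim")

#: Columns that are textual codes; forced to str on read so that e.g. a
#: species code "0" survives the CSV round trip unchanged.
_STR_COLS = {
    "plots": ["vegetation_type"],
    "trees": ["species", "species_group", "status"],
    "smalltrees": ["subplot"],
    "regen": ["subplot"],
    "deadwood": ["transect_id", "species_group"],
    "berry": ["quadrat", "species"],
}

_BUNDLE_SCHEMAS = {
    "plots": ["plot_id", "x", "y", "droppings", "vegetation_type", "n_parts"],
    "trees": ["plot_id", "part_id", "tree_id", "species", "species_group",
              "dbh_cm", "height_m", "status", "distance_m", "azimuth_deg"],
    "smalltrees": ["plot_id", "subplot", "n_class1", "n_class2"],
    "regen": ["plot_id", "subplot", "n_trees"],
    "deadwood": ["plot_id", "transect_id", "species_group", "decay_class",
                 "length_m", "diameter_cm", "d_root_cm", "d_cross_cm", "d_top_cm"],
    "berry": ["plot_id", "quadrat", "species", "cover"],
}


# ---------------------------------------------------------------------------
# landscape serialization


def write_landscape(landscape: Landscape, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landscape.trees.to_csv(out / "trees.csv", index=False)
    landscape.deadwood.to_csv(out / "deadwood.csv", index=False)
    landscape.elevation.to_ascii(out / "elevation.asc")
    features = []
    for (_, row), geom in zip(landscape.stands.iterrows(), landscape.stand_geoms):
        props = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in row.items()}
        features.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    gj = {"type": "FeatureCollection", "features": features}
    (out / "stands.geojson").write_text(json.dumps(gj, sort_keys=True))
    cfg = dataclasses.asdict(landscape.config)
    cfg["elevation_variogram"] = dataclasses.asdict(landscape.config.elevation_variogram)
    cfg["epoch_written"] = landscape.epoch
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_landscape_tables(in_dir) -> dict:
    """Read the landscape artifacts back as plain tables/objects (real-data
    mode consumes the same formats)."""
    p = Path(in_dir)
    gj = json.loads((p / "stands.geojson").read_text())
    stands = pd.DataFrame([f["properties"] for f in gj["features"]])
    geoms = [shape(f["geometry"]) for f in gj["features"]]
    return {
        "trees": pd.read_csv(p / "trees.csv"),
        "deadwood": pd.read_csv(p / "deadwood.csv"),
        "elevation": Raster.from_ascii(p / "elevation.asc"),
        "stands": stands,
        "stand_geoms": geoms,
        "config": yaml.safe_load((p / "config.yaml").read_text()),
    }


# ---------------------------------------------------------------------------
# plot observation bundles


def bundle_tables(observations: list[pp.PlotObservation]) -> dict[str, pd.DataFrame]:
    """Flatten plot observations into the CSV table bundle."""
    plots, trees, small, regen, dead, berry = [], [], [], [], [], []
    for obs in observations:
        plots.append({
            "plot_id": obs.plot_id, "x": obs.geometry.center[0], "y": obs.geometry.center[1],
            "droppings": obs.droppings, "vegetation_type": obs.vegetation_type,
            "n_parts": len(obs.parts),
        })
        for df, acc in ((obs.trees, trees), (obs.smalltrees, small), (obs.regen, regen),
                        (obs.deadwood, dead), (obs.berry, berry)):
            d = df.copy()
            d.insert(0, "plot_id", obs.plot_id)
            acc.append(d)

    def cat(frames, name):
        frames = [f for f in frames if len(f)]
        if frames:
            return pd.concat(frames, ignore_index=True)
        return pd.DataFrame(columns=_BUNDLE_SCHEMAS[name])

    return {
        "plots": pd.DataFrame(plots, columns=_BUNDLE_SCHEMAS["plots"]) if plots
        else pd.DataFrame(columns=_BUNDLE_SCHEMAS["plots"]),
        "trees": cat(trees, "trees"),
        "smalltrees": cat(small, "smalltrees"),
        "regen": cat(regen, "regen"),
        "deadwood": cat(dead, "deadwood"),
        "berry": cat(berry, "berry"),
    }


def write_plot_tables(tables: dict[str, pd.DataFrame], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _BUNDLE_SCHEMAS:
        tables[name].to_csv(out / f"{name}.csv", index=False)


def read_plot_tables(in_dir) -> dict[str, pd.DataFrame]:
    p = Path(in_dir)
    out = {}
    for name, required in _BUNDLE_SCHEMAS.items():
        df = pd.read_csv(p / f"{name}.csv",
                         dtype={c: str for c in _STR_COLS[name]},
                         keep_default_na=False, na_values=[""])
        for col in required:
            if col not in df.columns:
                raise ValueError(f"table {name!r}: missing column {col!r}")
        out[name] = df
    return out


def roundtrip_plot_tables(tables: dict[str, pd.DataFrame], tmp_dir) -> dict[str, pd.DataFrame]:
    """Write then read the bundle; the result is value-identical."""
    write_plot_tables(tables, tmp_dir)
    return read_plot_tables(tmp_dir)


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    out_dir: str = "nfisim_run"
    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    grid_origin: tuple[float, float] | None = None  # None: seeded-random phase
    baf_ladder: tuple = pp.BAF_LADDER
    season_start_doy: int = 152
    alpine_threshold_m: float = 900.0
    coefficients_file: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ls = raw.pop("landscape", {})
        vg = ls.pop("elevation_variogram", None)
        if vg:
            ls["elevation_variogram"] = SphericalVariogram(**vg)
        for key in ("extent", "deadwood_diam_weibull"):
            if key in ls:
                ls[key] = tuple(ls[key])
        if "species_mix" in ls:
            ls["species_mix"] = {int(k): tuple(v) for k, v in ls["species_mix"].items()}
        if raw.get("baf_ladder") is not None:
            raw["baf_ladder"] = tuple(raw["baf_ladder"])
        if raw.get("grid_origin") is not None:
            raw["grid_origin"] = tuple(raw["grid_origin"])
        raw.pop("epoch_written", None)
        return cls(landscape=LandscapeConfig(**ls), **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["landscape"]["elevation_variogram"] = dataclasses.asdict(
            self.landscape.elevation_variogram
        )
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest_path(out: Path) -> Path:
    return out / "manifest.json"


def _load_manifest(out: Path) -> dict:
    p = _manifest_path(out)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _record_stage(out: Path, manifest: dict, stage: str, files: list[Path], seed: int) -> None:
    manifest["stages"][stage] = {
        "completed": True,
        "seed": seed,
        "files": {str(f.relative_to(out)): _hash_file(f) for f in files},
    }
    _manifest_path(out).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _stage_done(out: Path, manifest: dict, stage: str) -> bool:
    info = manifest["stages"].get(stage)
    if not info or not info.get("completed"):
        return False
    return all((out / f).exists() for f in info["files"])


def predict_plot_volume_per_ha(
    obs: pp.PlotObservation, allometry: dm.AllometrySet
) -> float:
    """Run the full volume chain on one plot: h-tree selection, correction
    factors, corrected volumes; returns live growing stock in m^3/ha."""
    live = obs.trees[obs.trees["status"] == "live"].reset_index(drop=True)
    if len(live) == 0:
        return 0.0
    sel = pp.select_h_trees(live["dbh_cm"], live["distance_m"])
    h = sel.selected
    corrections = dm.plot_correction_factors(
        obs.plot_id,
        live.loc[h, "species_group"],
        live.loc[h, "dbh_cm"],
        live.loc[h, "height_m"],  # measured heights on the h-trees
        sel.weights[h],
        allometry,
        species_codes=live.loc[h, "species"],
    )
    total = 0.0
    for i, row in live.iterrows():
        corr = corrections.get(
            row["species_group"],
            dm.CorrectionContext(obs.plot_id, row["species_group"], 1.0, "fallback"),
        )
        v, _ = dm.predict_tree_volume(
            row["species"], row["dbh_cm"], allometry,
            measured_height_m=row["height_m"] if h[i] else None,
            correction=corr,
        )
        total += v
    return total / (pp.TREE_PLOT_AREA_M2 / 1e4)


def run_pipeline(config: RunConfig) -> Path:
    """simulate -> sample -> measure -> estimate, with manifest + resume."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out)
    rng = np.random.default_rng(config.seed)

    # --- simulate ---------------------------------------------------------
    ls_dir = out / "landscape"
    if not _stage_done(out, manifest, "simulate"):
        log.info("stage simulate: generating landscape (seed %d)", config.seed)
        lcfg = dataclasses.replace(config.landscape, seed=config.seed)
        landscape = simulate_landscape(lcfg)
        write_landscape(landscape, ls_dir)
        _record_stage(out, manifest, "simulate",
                      sorted(ls_dir.glob("*")), config.seed)
    else:
        log.info("stage simulate: already complete, skipping")
        lcfg = dataclasses.replace(config.landscape, seed=config.seed)
        landscape = simulate_landscape(lcfg)

    # --- sample -----------------------------------------------------------
    samp_dir = out / "design"
    samp_dir.mkdir(exist_ok=True)
    xmin, ymin, xmax, ymax = landscape.config.extent
    if config.grid_origin is not None:
        origin = config.grid_origin
    else:
        o_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
        origin = tuple(o_rng.uniform(0.0, sd.BASE_SPACING_M, 2))
    spacing = min(sd.BASE_SPACING_M, (xmax - xmin) / 2.0, (ymax - ymin) / 2.0)
    coords = sd.generate_grid(landscape.config.extent, spacing, origin)
    rules = sd.StratumRules(alpine_threshold_m=config.alpine_threshold_m,
                            grid_origin=origin)
    blocks = sd.tessellate_latin_squares(landscape.config.extent)
    locations = []
    for i, (x, y) in enumerate(coords):
        stratum = sd.assign_stratum((x, y), landscape.elevation, rules)
        panel = 1
        for b in blocks:
            bx0, by0, bx1, by1 = b.extent
            if bx0 <= x < bx1 and by0 <= y < by1:
                panel = b.panel
                break
        locations.append(sd.PlotLocation(i, x, y, stratum, panel))
    loc_df = pd.DataFrame(
        [{"id": l.id, "x": l.x, "y": l.y,
          "stratum": -1 if l.stratum is None else l.stratum,
          "panel": l.panel, "is_reserve_extra": l.is_reserve_extra}
         for l in locations]
    )
    if not _stage_done(out, manifest, "sample"):
        log.info("stage sample: %d grid locations", len(locations))
        loc_df.to_csv(samp_dir / "locations.csv", index=False)
        _record_stage(out, manifest, "sample", [samp_dir / "locations.csv"], config.seed)

    # --- measure ----------------------------------------------------------
    meas_dir = out / "plots"
    sampled = [l for l in locations if l.stratum is not None]
    observations = []
    for loc in sampled:
        geom = pp.layout_plot((loc.x, loc.y))
        try:
            obs = pp.measure_plot(landscape, geom, plot_id=loc.id)
        except ValueError:
            continue
        observations.append(obs)
    if not _stage_done(out, manifest, "measure"):
        log.info("stage measure: %d plots", len(observations))
        tables = bundle_tables(observations)
        write_plot_tables(tables, meas_dir)
        _record_stage(out, manifest, "measure",
                      sorted(meas_dir.glob("*.csv")), config.seed)

    # --- estimate ---------------------------------------------------------
    est_dir = out / "estimates"
    est_dir.mkdir(exist_ok=True)
    if not _stage_done(out, manifest, "estimate"):
        allo = (dm.AllometrySet.from_yaml(config.coefficients_file)
                if config.coefficients_file else dm.AllometrySet())
        strata_of = {}
        forest_by, vol_by, dw_by = {}, {}, {}
        for loc, obs in zip(sampled, observations):
            h = loc.stratum
            strata_of[loc.id] = h
            forest = landscape.forest_at(loc.x, loc.y)
            forest_by.setdefault(h, []).append(1.0 if forest else 0.0)
            vol_by.setdefault(h, []).append(
                predict_plot_volume_per_ha(obs, allo) if forest else 0.0
            )
            dw_by.setdefault(h, []).append(
                est.lis_plot_volume(obs.deadwood["diameter_cm"].to_numpy())
            )
        results = []
        if forest_by:
            f_frame = est.StratumFrame({h: np.array(v) for h, v in forest_by.items()})
            results.append(est.proportion_with_se(f_frame, "forest_share"))
            results.append(est.expand_total(
                est.StratumFrame({h: np.array(v) for h, v in vol_by.items()}),
                "growing_stock", "m3"))
            dw_vals = np.concatenate([np.array(v) for v in dw_by.values()])
            results.append(est.EstimationResult(
                "deadwood_mean", float(dw_vals.mean()),
                float(dw_vals.std(ddof=1) / np.sqrt(len(dw_vals))) if len(dw_vals) > 1 else 0.0,
                len(dw_vals), "lis", "m3/ha"))
        est_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        est_df.to_csv(est_dir / "estimates.csv", index=False)
        log.info("stage estimate: wrote %d estimates", len(est_df))
        _record_stage(out, manifest, "estimate", [est_dir / "estimates.csv"], config.seed)
    return out
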