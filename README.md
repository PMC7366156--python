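# nfisim

Simulation and estimation toolkit for a grid-based national forest
inventory (NFI) of the Nordic type, written for forest biometricians and
survey statisticians who want to study the design end to end without any
field data: a synthetic landscape generator, the sampling design
(stratified multi-resolution grids with Latin-square panels), the nested
plot measurement protocol, the tree-level dendrometric prediction chain,
and the design-based estimators that turn plot records into regional
statistics with standard errors.

## What it implements

**Sampling design.** Permanent plots on a 3 km × 3 km grid, tessellated
into 45 km × 45 km Latin squares of 5 × 5 blocks (81 km² each, 9 plot
locations per block).  The panel number of block (i, j) is
(i + 2j) mod 5 + 1, which is a Latin square and guarantees that no two
edge-adjacent blocks anywhere in the tiling are measured in the same year.
Four strata thin the grid — lowland 3 × 3 km (weight 9 km²/plot), alpine
3 × 9 km (27), productive far-north 3 × 3 km (9), remaining far-north
9 × 9 km (81) — and stratum membership away from mapped regions is
interpolated by universal kriging of the stratum indicator with
logit-transformed elevation as the trend covariate (spherical variogram;
the operational model has zero nugget, sill 0.73, range 5600 m).  Extra
plots 1.5 km north and east of base plots densify forest reserves.

**Plot protocol.** Nested circular units around one centre: trees with
dbh ≥ 5 cm on 250 m² (radius 8.92 m), stand variables on 0.1 ha, key
habitats on 0.2 ha, regeneration on five 16 m² subplots, small trees on
four 5.3 m² circles, berry cover on 0.25 m² quadrats, downed deadwood along
two 18 m transects, droppings on 100 m².  Plots near stand borders split
into at most two parts (smaller part ≥ 37.5 m² = 15%).  Heights are
measured on an angle-count subsample of ≈ 10 trees (h-trees), selected
with probability proportional to basal area.

**Dendrometry.** For non-h-trees a height is approximated from the h–dbh
curve, the volume v(dbh, h) is multiplied by the plot/species-group
correction factor

  f = Σᵢ wᵢ v(dᵢ, hᵢ_meas) / Σᵢ wᵢ v(dᵢ, hᵢ_approx),  wᵢ = 1/πᵢ,

with πᵢ the angle-count selection probability, and the final height is
recovered by solving the volume function for h.  Increment uses the dbh
one year back, dbh₋₁ = dbh − Δdbh/seasons, where the number of growing
seasons between two measurement dates (100-day season) lies in
[4.00, 6.00] over a 5-year cycle; removed trees get v_prev plus 2.5 years
of the previous increment.  Site index (H40 classes, 3 m bins), basal-area
weighted stand age, and a maturity-class table (entry ages decreasing in
site index within the printed ranges) classify stands.

**Estimation.** Stratified expansion totals (Σ_h w_h·100·Σ y_i for per-ha
plot values) and proportions with deliberately conservative SRS variances;
line intersect sampling of downed deadwood, v̂ = π²/(8L)·Σ dᵢ²·10⁴ m³/ha;
and synthetic small-area harvest estimates that aggregate a volume raster
over change-mask cells at 80% utilization.

Published coefficient sets of the operational allometric functions are not
shipped; the package provides documented stand-in coefficients of the same
functional families (Näslund height curve, power-law volume, log-ratio
biomass), loadable from YAML.

## Worked example

```python
from nfisim import StratumFrame, proportion_with_se, lis_plot_volume
import numpy as np

table = {1: (149_885.0, 11_046, 99_551.0), 2: (125_281.0, 442, 11_906.0),
         3: (1_350.0, 120, 1_080.0), 4: (47_266.0, 118, 9_683.0)}
values, weights, areas = {}, {}, {}
for h, (area, n_forest, forest_area) in table.items():
    w = forest_area / n_forest
    values[h] = np.concatenate([np.ones(n_forest),
                                np.zeros(round(area / w) - n_forest)])
    weights[h], areas[h] = w, area
res = proportion_with_se(StratumFrame(values, weights_km2=weights,
                                      areas_km2=areas))
print(f"{100 * res.estimate:.1f}% forest ({res.n_plots} plots)")
print(f"{lis_plot_volume([10.0], 36.0):.3f} m^3/ha")
```

prints

```
37.7% forest (22008 plots)
3.427 m^3/ha
```

— the 2014–2018 stratum table reconstructed into per-plot indicators
recovers the printed national forest share (37.7% of 323,782 km²), and a
single 10 cm deadwood piece crossing 36 m of transect contributes
3.427 m³/ha by the line-intersect formula.  The `examples/` directory has
one narrative script per capability (landscape generation, design layout,
plot measurement, estimation, the full pipeline); a thin CLI
(`nfisim run|simulate|sample|measure|estimate|report`) drives the same
pipeline from the shell.

## Layout

```
src/nfisim/       variogram, raster, sampling, plots, dendrometry,
                  landscape, estimation, io, cli
examples/         one short script per capability
docs/methods.md   models, assumptions, parameter choices, limitations
docs/data_dictionary.md  column-level schema of the plot tables
tests/            pytest suite (unit, property, acceptance)
```
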