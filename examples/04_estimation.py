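"""Design-based estimation: stratified proportions and line intersect
sampling.

The first part reconstructs the published stratum table (land areas, plots
in forest, forest areas of the 2014-2018 cycle) into per-plot indicators and
recovers the printed forest shares.  The second part evaluates the
line-intersect estimator on a hand-checkable case.
"""

import numpy as np

from nfisim import StratumFrame, lis_plot_volume, proportion_with_se

STRATUM_TABLE = {  # land area km^2, plots in forest, forest area km^2
    1: (149_885.0, 11_046, 99_551.0),
    2: (125_281.0, 442, 11_906.0),
    3: (1_350.0, 120, 1_080.0),
    4: (47_266.0, 118, 9_683.0),
}

values, weights, areas = {}, {}, {}
for h, (area, n_forest, forest_area) in STRATUM_TABLE.items():
    w = forest_area / n_forest  # implied km^2 represented per plot
    n_h = round(area / w)
    values[h] = np.concatenate([np.ones(n_forest), np.zeros(n_h - n_forest)])
    weights[h], areas[h] = w, area

frame = StratumFrame(values, weights_km2=weights, areas_km2=areas)
res = proportion_with_se(frame)
print(f"national forest share: {100 * res.estimate:.1f}% "
      f"(SE {100 * res.se:.2f} pp, {res.n_plots} plots)")
# expected: 37.7% of the land area is forest

s1 = StratumFrame({1: values[1]}, weights_km2=weights, areas_km2={1: areas[1]})
r1 = proportion_with_se(s1)
print(f"stratum-1 forest share: {100 * r1.estimate:.1f}%  (expected 66.4%)")

# line intersect sampling: one 10 cm piece crossing 36 m of transect
v = lis_plot_volume([10.0], 36.0)
print(f"LIS plot volume for a single 10 cm intersection: {v:.3f} m^3/ha "
      "(pi^2/(8*36) * 0.1^2 * 1e4)")
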