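"""Measure one permanent plot and run the volume prediction chain.

Trees >= 5 cm dbh are tallied on the 250 m^2 circle; about 10 of them are
selected for height measurement by an angle gauge (selection probability
proportional to basal area); the remaining trees get model heights whose
volumes are corrected by the plot-level ratio of measured-height to
approximated-height volume sums.
"""

from nfisim import AllometrySet, LandscapeConfig, layout_plot, measure_plot, simulate_landscape
from nfisim.io import predict_plot_volume_per_ha
from nfisim.plots import select_h_trees

cfg = LandscapeConfig(extent=(0, 0, 400, 400), cell_size=50.0, seed=3,
                      alpine_threshold_m=2000.0, forest_fraction={1: 1.0})
ls = simulate_landscape(cfg)

obs = measure_plot(ls, layout_plot((200.0, 200.0)), plot_id="demo")
print(f"trees tallied on 250 m^2: {len(obs.trees)}")

sel = select_h_trees(obs.trees["dbh_cm"], obs.trees["distance_m"])
print(f"h-trees selected: {sel.n_selected} (basal area factor {sel.baf_m2ha})")

allo = AllometrySet()
vol = predict_plot_volume_per_ha(obs, allo)
print(f"predicted growing stock on this plot: {vol:.1f} m^3/ha")

print(f"deadwood transect intersections: {len(obs.deadwood)}")
print(f"small-tree counts by subplot:\n{obs.smalltrees.to_string(index=False)}")
# The m^3/ha figure is the quantity the expansion estimator aggregates
# into stratum and national growing-stock totals.
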