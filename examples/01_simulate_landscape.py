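"""Generate a synthetic forest landscape and summarize what it contains.

The generator draws an elevation-like covariate (Gaussian field with a
spherical variogram on the logit scale), tessellates the extent into
Voronoi stands, and populates forest stands with individual trees and
downed deadwood.
"""

from nfisim import LandscapeConfig, simulate_landscape

cfg = LandscapeConfig(
    extent=(0.0, 0.0, 1000.0, 1000.0),  # 100 ha
    cell_size=50.0,
    alpine_threshold_m=1200.0,
    seed=42,
)
ls = simulate_landscape(cfg)

forest = ls.stands[ls.stands["land_use"] == "forest"]
live = ls.live_trees()
print(f"stands: {len(ls.stands)} ({len(forest)} forest)")
print(f"forest area: {ls.forest_area_m2() / 1e4:.1f} ha of 100 ha")
print(f"live stems >= 5 cm dbh: {len(live)}")
print(f"growing stock: {ls.total_volume_m3():.0f} m^3 "
      f"({ls.total_volume_m3() / (ls.forest_area_m2() / 1e4):.0f} m^3/ha of forest)")
print(f"downed deadwood pieces: {len(ls.deadwood)} "
      f"({ls.downed_deadwood_volume_m3():.1f} m^3 in total)")
# The per-ha growing stock should sit in the usual boreal range
# (roughly 50-250 m^3/ha depending on the maturity-class lottery).
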