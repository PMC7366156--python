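"""Lay out the sampling design: Latin squares, the 3 km grid, strata.

One 45 km x 45 km Latin square holds 25 blocks of 81 km^2; each block
contains 9 plot locations of the 3 km x 3 km grid and is assigned to one of
5 annual measurement panels such that panels balance across block rows and
columns and no two adjacent blocks share a panel.
"""

import numpy as np

from nfisim import (
    SphericalVariogram,
    StratumRules,
    assign_stratum,
    block_plot_locations,
    tessellate_latin_squares,
)
from nfisim.raster import Raster

blocks = tessellate_latin_squares((0, 0, 45000, 45000))
print(f"blocks in one Latin square: {len(blocks)}")
print(f"block area: {blocks[0].area_km2:.0f} km^2, "
      f"locations per block: {len(block_plot_locations(blocks[0]))}")

panel_matrix = np.zeros((5, 5), dtype=int)
for b in blocks:
    panel_matrix[b.block_index] = b.panel
print("panel matrix (rows = south to north):")
print(panel_matrix)

# stratum assignment against a toy elevation surface: plots above the
# alpine threshold stay in the sample only on the 3 km x 9 km sub-lattice
rng = np.random.default_rng(1)
elev = Raster(rng.uniform(200, 900, (15, 15)), 0.0, 0.0, 3000.0)
rules = StratumRules(alpine_threshold_m=600.0)
counts = {}
for b in blocks:
    for x, y in block_plot_locations(b):
        s = assign_stratum((x, y), elev, rules)
        counts[s] = counts.get(s, 0) + 1
print("plots per stratum (None = alpine nodes off the coarse grid,"
      " excluded):", counts)
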