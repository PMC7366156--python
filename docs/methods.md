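# Methods

This note documents the models behind `nfisim`, the defaults and why they
were chosen, what the synthetic landscapes do and do not emulate, and the
numerical choices that matter for reproducing results.

## Scope and coordinates

Everything lives in a projected planar coordinate system in metres,
(x east, y north).  Rasters use the cell-centre convention with row 0 at
the north; areas are m² internally and reported in ha or km² at the
interfaces.  All randomness flows through `numpy.random.Generator` objects
derived from a single integer seed, so every simulation, measurement and
pipeline run is bit-reproducible.

## Geostatistics

The spherical semivariogram γ(h) = c₀ + c·(1.5 h/a − 0.5 (h/a)³) for
h ≤ a (sill c₀ + c beyond) is the single covariance family used, with the
operational stratum-map parameters (nugget 0, sill 0.73, range 5600 m) as
defaults for the elevation covariate.  Three numerical choices:

- **Field simulation** is exact (Cholesky of the dense covariance, with a
  1e-10·sill diagonal jitter) for up to ~4,000 points.  Finer rasters are
  simulated on a coarse auxiliary lattice and refined bilinearly; with
  kilometre-scale ranges and 16–100 m cells the interpolation error is far
  below the field's own variability, and the exact path remains available
  for covariance-level checks.  An extent smaller than the range triggers
  a warning (the range is then not identifiable from one realization) but
  still returns a field.
- **Variogram fitting** is weighted least squares (weights √n_pairs) with
  non-negativity bounds; a numerically-zero nugget is snapped to exactly 0
  so the exact-interpolation property of downstream kriging holds.  An
  all-zero empirical variogram degenerates to a zero-sill model with a
  warning rather than an error.
- **Universal kriging** uses the bordered system with trend basis
  [1, covariate].  Coincident observations are averaged (the documented
  deduplication rule), collinear trend columns are dropped to keep the
  system non-singular, and beyond 2,000 observations each prediction uses
  its 500 nearest neighbours.  With zero nugget the predictor interpolates
  exactly at data points; probability maps are clipped to [0, 1] before
  the 0.5 threshold.

The kriged stratum map cannot beat the information content of the data:
the spherical field is mean-square continuous but not differentiable, so
the alpine/lowland contour wiggles below the 3 km sampling scale and a
misclassification floor of roughly 10–15% of cells (concentrated near the
contour) is inherent, not a defect.  The stated tolerance in the test
suite is 20%.

## Sampling design

The panel Latin square is the cyclic square panel(i, j) = (i + 2j) mod
5 + 1.  Because 2 is invertible mod 5 it is Latin, and because row and
column neighbours differ by 1 and 2 (mod 5) respectively — including
across the boundaries of the repeating 45 km tiling — no two edge-adjacent
81 km² blocks share a panel.  The national pattern is not published; any
fixed Latin square with the non-adjacency property is equivalent for the
design properties tested here.

Grid inclusion is half-open (west/south edges in, east/north out), so
tilings partition the plane without double-counting.  The coarse-lattice
phase for strata 2 and 4 (which base-grid rows/columns belong to the 9 km
grid) is configuration, default phase 0.  Sampling weights are stored as
the exact planar values 9/27/9/81 km² per plot: the published ~82 km² for
the sparsest stratum reflects meridian convergence of the real geographic
grid, which a planar synthetic landscape does not have; an override table
accepts official weights in real-data mode.  For design-unbiasedness
experiments the grid origin is randomized uniformly within one grid cell
per replicate; real-data mode uses a fixed origin.

## Synthetic landscapes

The generator's job is to give every downstream stage inputs with the
statistical structure the design assumes, not to be a forest growth model.

- **Elevation**: Gaussian field on the logit scale mapped by the logistic
  function to [0, 1500] m (the inverse of the logit transform used for the
  kriging covariate; the affine ceiling is a fixed artifact choice).
- **Stands**: Voronoi cells of Poisson seed points (default mean stand
  2 ha) — space-filling, convex, controllable in size.  Per stand:
  stratum from the elevation threshold, forest with the stratum's forest
  fraction, dominant species drawn from the stratum species mix, site
  index from a fixed class distribution, maturity class and an age
  uniform within that class's plausible span.  Default species mixes and
  forest fractions are the published 2014–2018 stratum-level values
  (e.g. the sparsest stratum: 0/4.2/94.9% spruce/pine/deciduous with
  20.5% forest).
- **Trees**: homogeneous Poisson positions within stands (the spatial
  distribution within stands is unspecified in the source protocol, so
  the simplest null model is used); dbh = 5 cm + Weibull(1.8, 10 cm);
  within-stand species fidelity 90% to the dominant group; heights on the
  h–dbh curve times a persistent lognormal factor (σ = 0.08) so repeated
  measurements of one tree stay on one curve; 3% standing dead.
  Densities per maturity class (1100/900/600/400 stems ha⁻¹ for classes
  2–5) are generic boreal values.
- **Deadwood**: 20 pieces ha⁻¹, length U(2, 10) m, root diameter
  5 + Weibull(1.6, 8) cm, top diameter a U(0.2, 0.6) fraction of the
  root, uniform orientation.  Piece volume truth uses the conical frustum
  (equivalently (π/4)∫d² along the linear taper), which is exactly the
  quantity the line-intersect estimator is unbiased for.
- **Dynamics**: annual steps — dbh growth N(0.3, 0.1) cm yr⁻¹ truncated
  at 0, mortality 0.005 yr⁻¹, stand harvest probability 0.05 per 5 years
  converted to an annual rate (harvest removes all live stems and resets
  stand age), ingrowth 5 stems ha⁻¹ yr⁻¹ appearing at the 5 cm
  threshold.  Stems never leave the table; statuses partition into
  live/dead/removed with the epoch of death or removal recorded.

What the generator does *not* emulate: climate- or competition-sensitive
growth, spatial clustering of trees within stands, irregular stand
borders (splits use straight chords), measurement error, or the
geographic trends of a real country.  Passing tests therefore demonstrate
the internal consistency and design-based properties of the machinery
(unbiasedness over the randomization the design actually controls), not
predictive skill on real forests.

## Plot protocol

Boundary conventions: closed-disc inclusion (distance ≤ radius) and an
inclusive 5.00 cm dbh threshold.  Split-part areas are closed-form
circular segments; attribute contrast triggering a split is
maturity-class, site-index or land-use difference.  The h-tree
basal-area-factor ladder (0.5, 1, 2, 3, 4, 6, 9 m² ha⁻¹) and the rule
"smallest factor whose expected count ≤ 10" are artifact choices — the
field protocol only specifies a factor derived from the previous visit.
The angle-count selection probability used for correction-factor weights
is πᵢ = min(1, (limitᵢ/R)²) with limitᵢ = dbhᵢ(m)·50/√BAF and R the plot
radius: the probability that a uniformly positioned stem falls inside its
own inclusion circle, proportional to basal area and capped at certainty;
when ≤ 10 trees are present all are measured and weights are uniform.

Key-habitat rules are density thresholds per hectare evaluated on the
0.2 ha plot with distance chaining (union–find; a patch qualifies if its
object count reaches threshold × 0.2 ha).  Regional variants (20 vs
60 trees ha⁻¹ and 25 vs 15 m for nutrient-rich bark; aspen-only in the
north) are configuration.  Missing optional attributes (lichen flags,
ages) make a category *not assessed*, distinct from absent.

## Dendrometry

Stand-in allometry families: height h = 1.3 + (d/(a + b·d))³ (asymptote
1.3 + b⁻³ m), volume v = a·d^b·h^c with c > 0 enforced so v is strictly
increasing in h (required for back-solving), biomass
ln B = c₀ + c₁·d/(d + k).  Species routing follows the operational
mapping: spruce and firs to the spruce set except Sitka spruce (own set),
all other conifers to pine, all broadleaves to the deciduous set.
Coefficients live in a dict/YAML so published sets can be dropped in; all
chain-level tests are allometry-agnostic (ratios, round trips, simulated
truths).

Numerical choices: height back-solving uses Brent's method on an
auto-expanding bracket, converged to |Δv| < 1e-9 m³ (≪ the documented
1 mm height round-trip); the correction factor is applied before the
breakage adjustment (the order is unspecified in the protocol; correction
first keeps the factor a pure height-model property).  Breakage is the
cone-top rule — a break at relative height r removes (1 − r)³ of the stem
volume — applied only when the diameter at the break is ≥ 10 cm, and
switchable off.

The growing-season count anchors the 100-day window to the calendar date
of the start day (default June 1) rather than a raw day-of-year so leap
years do not shift the window; only differences of the within-season day
count matter.  Ingrowth increment imputation widens its cell
hierarchically — drop site index, then the maturity group, then species
mean — and errors only when a species has no matched trees at all.

The maturity entry-age table interpolates linearly in site index between
the printed extremes (class 5: 120 yrs at SI 6 down to 40 yrs at SI 26;
class 4: 119→25; class 3: 84→15) and is audited at construction for
monotonicity in SI, ordering across classes, and containment in the
printed ranges.  The H40 ladder (6, 8, 11, 14, 17, 20, 23, 26) uses
midpoint boundaries with lower-inclusive bins, which reproduces the
printed class-14 bounds [12.5, 15.5).

## Estimation

Expansion totals use Σ_h w_h·100·Σᵢ yᵢ for per-ha plot values; the SE is
the within-stratum SRS variance scaled by the expansion, with the
finite-population correction off — both choices deliberately
conservative for the systematic design.  Single-plot strata are collapsed
into the nearest stratum id for variance only, with a warning.  When no
official stratum areas are supplied, A_h = n_h·w_h (self-consistent
expansion); official areas override, which is how the published stratum
table is reproduced exactly.  The conservatism of the SRS assumption
holds in the design's operating regime — grid spacing well above the
stand scale; at spacings below the stand size systematic samples are
positively autocorrelated and SRS variances can understate the truth,
which the test suite demonstrates by construction rather than hides.

Standing dead trees can enter estimates by either path — the 250 m² plot
expansion (they flow through the live-tree volume chain) or line
intersect sampling if fallen — and the two are labelled distinctly.
Reserve-densification plots are excluded from national expansion by
default (their inclusion rule in national weights is not published).

Synthetic small-area harvest: per region, utilization × Σ volume-per-ha ×
cell area over change-mask cells, default utilization 0.8 (20% of
standing volume assumed left in the forest); changed cells are zeroed in
the updated raster.  Mis-registered rasters are an error, empty regions
return 0.

## Problem sizes

The test and acceptance workloads are sized for a laptop-class single
core: landscapes of 9–100 ha with 50–150 m elevation cells, 200-replicate
design-unbiasedness runs, 300–400-replicate line-intersect checks, and
50-realization variogram recovery on a 21 × 21 grid of 3 km nodes.  These
sizes were chosen so Monte-Carlo tolerances (stated per test) are tight
enough to catch implementation errors while each suite stage runs in
seconds.

## Known limitations

- The package is a design laboratory, not an operational estimator: no
  model-assisted estimation with remote-sensing auxiliaries, no
  model-based small-area variances, no county-level temporary-plot
  pooling beyond the hooks.
- Stand-in allometric coefficients produce plausible but not calibrated
  volumes; absolute m³ figures from the synthetic pipeline are not
  comparable to published statistics.
- Plot splitting handles straight chords and at most two parts; real
  stand borders are irregular and field crews may split differently.
- The 0.2 ha key-habitat extent rule is taken from stand attributes
  rather than assessed beyond the plot boundary (no procedure is
  published for the field assessment either).
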