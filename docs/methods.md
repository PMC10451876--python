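# Methods

This note documents the models implemented in `ecocircuit`, the choices
made where the design was genuinely open, what the synthetic landscapes do
and do not emulate, and the package's numerical conventions and limits.

## Resistance surface

Ecological resistance is modeled as a per-cell cost assembled from four
factors: elevation (m), slope (degrees), terrain roughness, and land-use
type. Each factor is classified into the discrete resistance values
{10, 50, 100, 200, 400, 10000} by the assignment table in
`ecocircuit/data/table1.yaml`; the combined surface is the **arithmetic
mean** of the four factor values. The mean — rather than a sum — is the
only reading of "equal-weight superposition" consistent with the published
extremes this workflow is anchored to: a minimum of 10 (four lowest
classes) and a maximum of 7600 (three 10000-valued terrain classes plus the
400-valued land-use group). A `cap` argument can clip factor values before
averaging for sensitivity analysis against workflows that bound the extreme
class at 1000, but the default is uncapped: the anchored extremes are
internally consistent only with the uncapped table.

Conventions:

- Continuous class intervals are lower-closed, upper-open (`[a, b)`): a
  slope of exactly 15° falls in the 15–30 class, elevation 2000 m in the
  >2000 class. The table is configurable, so other conventions can be
  encoded by shifting breaks.
- **Slope** uses Horn's 3×3 finite-difference operator, the common GIS
  default, in degrees (the class bounds 10/15/30 read as degrees). Border
  cells replicate their nearest neighbours so the grid does not shrink.
- **Terrain roughness** is the surface-to-planar-area ratio
  `1/cos(slope)`, a dimensionless value ≥ 1. This definition is chosen
  because the class bounds 1.1–1.3 sit exactly in that statistic's natural
  range; alternative "roughness" definitions (e.g. relief amplitude) have
  incompatible units.
- Land-use codes follow a CNLUCC-style integer legend; the shipped mapping
  groups codes into the five resistance groups and is replaceable through
  `load_classification(path)`, so any similar legend can be bound without
  code changes.

## Circuit model

The landscape is a resistive network. Valid raster cells are nodes;
orthogonal neighbours are joined by a resistor equal to the mean of the two
cell resistances, diagonal neighbours (8-neighborhood, the default and the
dominant convention in circuit-theory connectivity software) by that mean
scaled by √2. All cells of one habitat patch are contracted into a single
zero-internal-resistance supernode; parallel edges created by contraction
merge by conductance summation. Patches of both types are terminals with
equal standing; an option restricts pairs to those touching a type-I patch
for the initial-dispersal scenario.

For each unordered patch pair, a nominal 1 A is injected at the source
supernode with the target grounded, and the grounded graph Laplacian is
solved with a sparse LU factorization (SuperLU via scipy), restricted to
the terminals' connected component; the factorization is reused across all
sources sharing a target. Outputs per pair:

- `R_eff = V_source / I`, the effective resistance (Ohm's law `I = V/R_eff`);
  it integrates every parallel route, unlike a least-cost path.
- A per-cell current density: half the sum of absolute currents on the
  cell's incident edges (each edge's current split between its endpoints);
  patch cells display their supernode's throughput, which for terminals is
  the injected current. Pairs in disconnected components return
  `R_eff = ∞` with a zero current map, flagged rather than raised.

Cumulative current maps sum the per-pair maps without per-pair
normalization (configurable in principle; raw summation is the default
because each pair injects the same nominal current). Conservation,
reciprocity, Rayleigh monotonicity, and agreement with the dense
pseudoinverse formula `R_eff = L⁺_ss + L⁺_tt − 2 L⁺_st` are enforced by the
test suite at 1e-8 tolerances. The dense-oracle cross-check uses
`numpy.linalg.pinv(..., hermitian=True)`; the non-hermitian SVD path is
measurably less accurate on these Laplacians.

## Jenks natural breaks

Corridor and pinch-point thresholds use Jenks natural-breaks
classification: the partition of a 1-D sample into k contiguous classes
minimizing total within-class squared deviation. The implementation is the
exact Fisher dynamic program (O(k n²)); samples larger than `max_exact_n`
(default 2000) are first reduced to a deterministic stratified subsample —
evenly spaced order statistics of the sorted data, endpoints included — and
the subsampling is recorded in the result. Exactness is verified against
exhaustive enumeration of all contiguous partitions for small samples.

**Corridors** are the top 2 of k = 10 classes of *positive* current
densities (zeros from masked or unreachable areas would meaninglessly
dominate the lowest class). Focal-patch interiors are excluded from
classification by default — their terminal throughput is an artifact of
injection, not passage — with a flag to include them. The reported
threshold is the lowest current density inside the mask; an absolute
`threshold` override supports fixed-cut workflows. Corridor "groups" are
8-connected components of the mask.

**Pinch points** are the top of k = 3 classes computed on current densities
*within* a 10 km planar buffer of the type-I patches (cell-center to
cell-center distance, via a Euclidean distance transform). The three levels
are scoped to the buffer rather than global (a `--global-breaks` style
choice is available by classifying externally); patch interiors are again
excluded, for the same reason as in the corridor stage.

**Validation** compares the fraction of observation points within a
tolerance (default 2 cells) of a pinch cell against a uniform-random null:
the same number of points is re-drawn uniformly over valid cells 1000 times
(seeded), and the null mean, 95th percentile and an empirical p-value are
reported. The null is deliberately reported separately from the point
estimate so a qualitative "points align with pinch points" claim and the
quantitative test are not conflated.

## Synthetic landscapes

Real inputs for this workflow (30–90 m national land-cover and DEM rasters,
reserve polygons, species early-warning points) are large and access
restricted. The `synthetic` module generates seeded stand-ins with the
statistical structure the pipeline assumes; every generator is a pure
function of (grid, parameters, seed).

- **DEM**: Gaussian-filtered white noise rescaled to
  `[base_elevation, base_elevation + relief]`; the `smoothness` parameter
  (filter σ in cells) monotonically increases spatial autocorrelation.
- **Land use**: a smooth random field thresholded at the cumulative
  quantiles of the requested group shares, so realized shares track the
  weights closely; a second smooth field lays out the codes within each
  group, giving contiguous mosaics rather than salt-and-pepper codes. The
  default mixture (30% shrub/grass, 35% forest/dry, 10% wet/rural, 15%
  woodland/paddy, 10% built/water) is a plausible southern-Yunnan-like
  composition; it makes no attempt to match real cover proportions.
- **Patches**: disjoint near-circular polygons by seeded rejection
  sampling, the first `n_type1` labeled type I; failure to place raises an
  error naming the patch rather than silently overlapping.
- **Warning points**: sampled with probability proportional to cell current
  density (plus within-cell jitter). Generating them *from* the current map
  plants a signal of known strength for the validation stage; real animal
  records would also carry avoidance behaviour, observation bias and
  autocorrelation that this generator does not emulate.

### The mountain-pass (channel) scene

The canonical planted-structure fixture is a 100×100 grid of 1 km cells —
so the 10 km type-I buffer is genuinely local — containing two square
patches on flat valley floors (700 m) in a high, rugged plateau
(1850–2450 m, mostly above the top elevation class; its steep valley walls
fall in the top slope and roughness classes). The patches are joined by a
single shrub valley shaped like an hourglass: a one-cell-wide pass flush
with the type-I patch face opens through short diagonal stairs into twin
one-cell-wide branches that rejoin the type-II patch. Because every segment
is a series path, the channel's current densities form exactly two tight
clusters — branches at half the injected current, the pass at the full
current — and the pass is simultaneously the narrowest cross-section and
the current maximum: a true planted pinch point.

A ten-class corridor scheme presumes the multi-scale current structure of
real landscapes (many routes of graded quality below the best corridor).
The scene therefore also plants, between the patches, three secondary
valley routes of graded quality (shrub paths degraded by increasing counts
of woodland/paddy cells) and a diffuse low-elevation mosaic shelf along the
southern edge fed through two long degraded access valleys; together these
populate the lower natural-breaks classes the way real cumulative current
maps do. This composition emerged from explicit sensitivity prototyping of
the classification stage: with a purely two-scale map (one channel in a
uniform matrix), within-class structure of the channel itself attracts
breaks, which is a property of the classifier, not of connectivity. The
design was frozen after verifying corridor recovery (100% channel coverage,
0.02% background false positives), pinch recovery (exactly the pass cells)
and validation power across 20 seeds.

What passing these tests shows — and does not. They demonstrate that the
pipeline recovers a known planted corridor and bottleneck under controlled
multi-scale conditions and that its statistics behave as designed. They do
not demonstrate that ten classes/top-two is optimal for any particular real
landscape, nor that real species follow circuit-theoretic current; those
are empirical questions outside a synthetic benchmark.

## Numerical choices and limitations

- Deterministic everything: generators, solver ordering, subsampling and
  Monte-Carlo draws are seeded; pipeline reruns are bit-identical (elapsed
  time is excluded from the written report).
- Sparse solves use LU factorization; for the ~10⁴-node scenes used here a
  solve takes well under a second. Much larger rasters would want an
  iterative solver with a preconditioner; none is included.
- Grids are planar with square cells; buffers use planar Euclidean
  distance. No geodesic handling, reprojection or sub-cell geometry.
- Raster I/O is the plain-text ESRI ASCII grid (single band, one nodata
  sentinel); vector I/O is GeoJSON. No GeoTIFF support — the format choice
  keeps every artifact diffable text readable by standard GIS tools.
- The pinch-point stage implements the buffer + three-level natural-breaks
  procedure only; hybrid variants that combine least-cost-path models with
  circuit theory are out of scope, as are corridor-width optimization,
  habitat-quality scoring for nominating type-II patches, and map styling.
- Problem sizes: the shipped scenes are 100×100 cells (≈10⁴ nodes, one to
  three patch pairs), chosen as the smallest landscapes that exhibit the
  full multi-scale phenomenology; all analyses scale to larger grids
  through the same API.
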