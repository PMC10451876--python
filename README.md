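# ecocircuit

Circuit-theory landscape connectivity analysis: build an ecological
resistance surface from terrain and land-use factors, map current density
between habitat patches with a resistive-grid model, and extract ecological
corridors and pinch points.

The package targets the planning problem faced in wildlife conservation —
for the motivating case, wild Asian elephants (*Elephas maximus*) in
southern Yunnan: given reserves that hold the species (type-I patches),
suitable alternative habitat (type-II patches), and a landscape that
resists movement to different degrees, where are animals most likely to
travel if they disperse, and where is their movement funneled through
narrow, irreplaceable bottlenecks? It is written for movement ecologists
and conservation planners who want a scripted, reproducible version of this
workflow, exercised end-to-end on synthetic landscapes so no restricted GIS
layers are required.

## The model

1. **Resistance surface.** Four factors — elevation, slope, terrain
   roughness (the surface-to-planar area ratio `1/cos(slope)`) and land-use
   type — are each classified into resistance values
   `{10, 50, 100, 200, 400, 10000}` by an assignment table (shipped as
   `ecocircuit/data/table1.yaml`, overridable). The combined per-cell
   resistance is their equal-weight superposition, i.e. the arithmetic
   mean: a cell in the three extreme terrain classes with 400-valued land
   use combines to `(10000 + 10000 + 10000 + 400)/4 = 7600`, and a cell in
   all lowest classes to `10`.
2. **Circuit model.** The raster becomes a resistive network: each valid
   cell is a node, neighbouring cells (8-neighborhood by default, diagonals
   scaled by √2) are joined by a resistor equal to the mean of the two cell
   resistances, and each patch is contracted to a zero-resistance
   supernode. A random-walking animal behaves like electrical current:
   injecting unit current between a patch pair and solving the graph
   Laplacian `G V = I` yields the effective resistance
   `R_eff = V_source / I` (Ohm's law, `I = V / R_eff`) — a measure of
   isolation that integrates **all** parallel pathways — and a per-cell
   current density (half the sum of incident absolute edge currents), the
   expected traffic of a random walker. Current maps are accumulated over
   all patch pairs.
3. **Corridors.** Positive current densities are split into ten Jenks
   natural-breaks classes (exact Fisher dynamic programming); the top two
   classes form the corridor mask, whose 8-connected components are the
   corridor groups and whose land-use composition is reported by zonal
   statistics.
4. **Pinch points.** Within a 10 km buffer of the type-I patches, current
   densities are split into three Jenks levels; the top level marks the
   pinch points — narrow areas where flow has no alternative route. An
   observation-point overlap test against a seeded uniform Monte-Carlo null
   quantifies agreement with field records.

## Worked example

The no-data quickstart runs the whole pipeline on the built-in
"mountain-pass" scene — two patches in a high, rugged plateau joined by a
single low-resistance valley with a one-cell-wide pass:

```bash
ecocircuit simulate-and-run --preset channel --seed 7 --out run7
```

or, from Python (as in `examples/03_current_and_reff.py` and
`examples/04_corridors_and_pinchpoints.py`):

```python
import ecocircuit as ec

scene = ec.channel_scene(seed=0)
resistance, _ = ec.build_resistance_surface(scene.dem, scene.landuse)
labels = ec.rasterize_patches(scene.patches, scene.spec)
graph = ec.build_graph(resistance, labels, neighborhood=8)
current = ec.accumulate_current(graph, scene.patches)
corridor = ec.extract_corridors(current, k=10, top_classes=2, patch_labels=labels)
buffer = ec.buffer_patches(scene.patches, labels, radius_m=10_000)
pinch = ec.extract_pinch_points(current, buffer, k=3, patch_labels=labels)
```

which prints (seed 0):

```
R_eff(patch 1 <-> 2) = 78.5 resistance units
current density in the planted valley: median 0.281 A
current density in the matrix:        median 3.61e-04 A
corridor: 30 cells (30.0 km^2) in 2 group(s)
  current-density threshold used: 0.1592 A
pinch points: 10 cells, 10.00 km^2 inside the 10 km type-I buffer
  located on the single-width pass: rows [50], cols 37-46
  fraction of points within 2 cells of a pinch point: 0.055
  uniform null: mean 0.006, 95th percentile 0.015  (p = 0.0010)
```

Read: the two patches are separated by ~78.5 resistance units once every
route is pooled; the planted valley carries three orders of magnitude more
simulated traffic than the surrounding plateau and is recovered as the
corridor; the single-width pass — where both valley branches funnel into
one line of cells — is flagged as the pinch point; and observation points
sampled from the current map cluster at that bottleneck far beyond what a
uniform null allows.

`examples/` holds one short narrative script per capability:
synthetic-landscape generation, resistance-surface construction, the
circuit solve, and corridor/pinch-point extraction.

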