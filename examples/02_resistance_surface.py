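"""Build the four-factor ecological resistance surface.

Derives slope and terrain roughness from the DEM, classifies elevation,
slope, roughness and land use into their resistance values, and combines
them by equal-weight superposition (the arithmetic mean of the four factor
values). Low values mark terrain an elephant crosses easily; the extreme
classes (high mountains, steep ground, built-up land and open water) push a
cell toward the 10,000-valued end.
"""

import numpy as np

import ecocircuit as ec

scene = ec.mosaic_scene(seed=42, nrows=100, ncols=100, cell_size=500.0)
combined, factors = ec.build_resistance_surface(scene.dem, scene.landuse)

vals = combined.valid_values
print("combined resistance surface:")
print(f"  min {vals.min():.1f}   mean {vals.mean():.1f}   max {vals.max():.1f}")
print("  (cell value = mean of the four classified factor values)")

r, c = np.unravel_index(np.argmax(combined.values), combined.values.shape)
print(f"\nmost resistant cell ({r},{c}):")
for name, raster in factors.items():
    print(f"  {name:10s} -> {raster.values[r, c]:.0f}")
print(f"  combined   -> {combined.values[r, c]:.1f}")

slope = ec.compute_slope(scene.dem)
rough = ec.compute_roughness(slope)
print(f"\nterrain factors: slope {slope.values.max():.1f} deg max, "
      f"roughness {rough.values.max():.3f} max (1.0 = flat)")
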