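"""Extract ecological corridors and pinch points from the current map.

Corridors = the top two of ten Jenks natural-breaks classes of positive
current density (the most-traveled routes). Pinch points = the top of three
Jenks levels inside a 10 km buffer of the type-I patch — narrow, irreplaceable
bottlenecks. Synthetic observation points drawn proportionally to current
density validate the pinch mask against a seeded uniform null.
"""

import numpy as np

import ecocircuit as ec
from ecocircuit.resistance import load_classification

cfg = load_classification()
scene = ec.channel_scene(seed=0)
combined, _ = ec.build_resistance_surface(scene.dem, scene.landuse)
labels = ec.rasterize_patches(scene.patches, scene.spec)
graph = ec.build_graph(combined, labels, neighborhood=8)
cm = ec.accumulate_current(graph, scene.patches)

corridor = ec.extract_corridors(cm, k=10, top_classes=2, patch_labels=labels)
comp = ec.zonal_composition(corridor.mask, scene.landuse, config=cfg)
fg = comp.loc[comp.group == "forest_grassland_total", "percent"].iloc[0]
print(f"corridor: {corridor.n_cells} cells ({corridor.area_km2:.1f} km^2) in "
      f"{corridor.n_groups} group(s)")
print(f"  current-density threshold used: {corridor.threshold_used:.4f} A")
print(f"  forest+grassland share of corridor area: {fg:.1f}%")

buffer = ec.buffer_patches(scene.patches, labels, radius_m=10_000.0)
pinch = ec.extract_pinch_points(
    cm, buffer, k=3, patch_labels=labels, landuse=scene.landuse,
    config=cfg, buffer_radius_m=10_000.0,
)
print(f"\npinch points: {pinch.n_cells} cells, {pinch.total_area_km2:.2f} km^2 "
      f"inside the 10 km type-I buffer")
rows, cols = np.nonzero(pinch.mask.values)
print(f"  located on the single-width pass: rows {sorted(set(rows.tolist()))}, "
      f"cols {cols.min()}-{cols.max()} (planted pass cols {scene.pinch_cols})")

points = ec.generate_warning_points(cm.raster, n=200, seed=1000)
report = ec.validate_points(pinch, points, tolerance_cells=2, n_null=1000, seed=2000)
print(f"\nobservation-point validation ({report['n_points']} points, "
      f"{report['n_null']} null draws):")
print(f"  fraction within {report['tolerance_cells']} cells of a pinch point: "
      f"{report['observed_fraction']:.3f}")
print(f"  uniform null: mean {report['null_mean']:.3f}, "
      f"95th percentile {report['null_q95']:.3f}")
print(f"  empirical p-value: {report['p_value']:.4f} — points sampled from the")
print("  current map cluster at the bottleneck far beyond chance")
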