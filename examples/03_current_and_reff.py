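"""Solve the resistive-network model between habitat patches.

The resistance raster becomes a conductance graph (8-neighborhood, patch
cells contracted to supernodes); injecting a unit current between a patch
pair and solving the graph Laplacian yields the effective resistance R_eff
(isolation integrating all parallel routes; I = V / R_eff) and a per-cell
current density map (expected random-walker traffic). The demo first checks
the solver against the series-resistor closed form, then maps current on
the mountain-pass scene.
"""

import numpy as np

import ecocircuit as ec

# closed-form sanity check: a chain of n cells of resistance r has
# R_eff = (n - 1) r between its end cells (4-neighborhood)
spec = ec.GridSpec(nrows=3, ncols=8, cell_size=100.0)
mask = np.zeros(spec.shape, dtype=bool)
mask[1, :] = True
labels = np.zeros(spec.shape, dtype=int)
labels[1, 0], labels[1, 7] = 1, 2
res = ec.Raster(np.full(spec.shape, 10.0), spec, mask=mask.copy())
lab = ec.Raster(labels, spec, mask=mask.copy())
chain = ec.solve_pair(ec.build_graph(res, lab, neighborhood=4), 1, 2)
print(f"chain of 8 cells, r=10: R_eff = {chain.effective_resistance:.1f} "
      f"(closed form {(8 - 1) * 10})")

# the planted mountain-pass scene: one low-resistance valley between patches
scene = ec.channel_scene(seed=0)
combined, _ = ec.build_resistance_surface(scene.dem, scene.landuse)
patch_labels = ec.rasterize_patches(scene.patches, scene.spec)
graph = ec.build_graph(combined, patch_labels, neighborhood=8)
cm = ec.accumulate_current(graph, scene.patches)

print(f"\nmountain-pass scene: {graph.n_nodes} nodes, "
      f"{cm.n_pairs} patch pair(s) solved")
print(f"R_eff(patch 1 <-> 2) = {cm.reff.loc[1, 2]:.1f} resistance units")

cur = cm.raster.values
inside = cur[scene.channel_mask]
outside = cur[(patch_labels.values == 0) & ~scene.channel_mask]
print(f"current density in the planted valley: median {np.median(inside):.3f} A")
print(f"current density in the matrix:        median {np.median(outside):.2e} A")
print("the valley carries orders of magnitude more simulated traffic —")
print("it is the migration route the corridor stage will extract")
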