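import numpy as np
import pytest

import ecocircuit as ec


@pytest.fixture
def spec10() -> ec.GridSpec:
    return ec.GridSpec(nrows=10, ncols=10, cell_size=100.0)


def uniform_raster(spec: ec.GridSpec, value: float, mask=None) -> ec.Raster:
    return ec.Raster(np.full(spec.shape, float(value)), spec, mask=mask)


def make_chain(n: int, r: float = 10.0):
    """A 1-D chain of n uniform-resistance cells with single-cell terminal
    patches at both ends, embedded in the middle row of a masked 3xn grid."""
    spec = ec.GridSpec(nrows=3, ncols=n, cell_size=100.0)
    mask = np.zeros(spec.shape, dtype=bool)
    mask[1, :] = True
    res = ec.Raster(np.full(spec.shape, r), spec, mask=mask.copy())
    labels = np.zeros(spec.shape, dtype=int)
    labels[1, 0] = 1
    labels[1, n - 1] = 2
    return res, ec.Raster(labels, spec, mask=mask.copy())


def random_instance(rng: np.random.Generator, max_side: int = 8):
    """Random masked resistance grid with two single-cell terminal patches;
    redraws until the terminals are in one connected component."""
    while True:
        nr = rng.integers(4, max_side + 1)
        nc = rng.integers(4, max_side + 1)
        spec = ec.GridSpec(nrows=int(nr), ncols=int(nc), cell_size=100.0)
        res_vals = np.exp(rng.normal(3.0, 1.0, size=spec.shape))
        mask = rng.random(spec.shape) > 0.2
        if mask.sum() < 4:
            continue
        cells = np.argwhere(mask)
        i, j = rng.choice(len(cells), size=2, replace=False)
        labels = np.zeros(spec.shape, dtype=int)
        labels[tuple(cells[i])] = 1
        labels[tuple(cells[j])] = 2
        res = ec.Raster(res_vals, spec, mask=mask.copy())
        lab = ec.Raster(labels, spec, mask=mask.copy())
        graph = ec.build_graph(res, lab, neighborhood=int(rng.choice([4, 8])))
        comp = graph.component_labels()
        if comp[graph.patch_node[1]] == comp[graph.patch_node[2]]:
            return graph


def dense_reff(graph, source: int, target: int) -> float:
    """Independent oracle: effective resistance from the dense Laplacian
    pseudoinverse, R = L+_ss + L+_tt - 2 L+_st."""
    lp = np.linalg.pinv(graph.laplacian.toarray(), hermitian=True)
    s, t = graph.patch_node[source], graph.patch_node[target]
    return float(lp[s, s] + lp[t, t] - 2 * lp[s, t])


@pytest.fixture(scope="session")
def channel_solution():
    """The seeded channel scene solved once for corridor/pinch-point tests."""
    scene = ec.channel_scene(seed=0)
    combined, factors = ec.build_resistance_surface(scene.dem, scene.landuse)
    labels = ec.rasterize_patches(scene.patches, scene.spec)
    graph = ec.build_graph(combined, labels, neighborhood=8)
    current = ec.accumulate_current(graph, scene.patches)
    return {
        "scene": scene,
        "resistance": combined,
        "labels": labels,
        "graph": graph,
        "current": current,
    }
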