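"""Resistive-network model of the landscape.

The resistance raster becomes an undirected conductance graph: every valid
cell is a node, orthogonal (and optionally diagonal) neighbours are joined
by a resistor equal to the mean of the two cell resistances (scaled by
sqrt(2) on diagonals), and all cells of one habitat patch are contracted
into a single zero-internal-resistance supernode. For each patch pair, a
unit current is injected at the source supernode with the target grounded;
solving the graph-Laplacian system yields node potentials, the effective
resistance R_eff = V_source / I (Ohm's law, I = V / R_eff), and a per-cell
current density map. Current maps accumulated over all patch pairs form the
ecological network: high-current cells are the likely movement routes of a
random walker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import factorized

from .grid import Raster
from .patches import PatchSet


class GraphError(ValueError):
    pass


class EmptyGraphError(GraphError):
    """No valid cell remains after masking."""


@dataclass
class ConductanceGraph:
    """Sparse conductance graph over raster cells with patch supernodes.

    Nodes 0..n_free-1 are free (non-patch) cells in row-major order of the
    valid cells; nodes n_free.. are one supernode per patch id (ascending).
    ``edges`` keeps one entry per raster cell adjacency (cell_a, cell_b flat
    indices and the node ids they map to) so edge currents can be painted
    back onto the grid; the Laplacian merges parallel edges automatically.
    """

    n_nodes: int
    node_of_cell: np.ndarray          # flat cell index -> node id (-1 = masked)
    patch_node: dict[int, int]        # patch id -> supernode id
    edge_cells: np.ndarray            # (m, 2) flat cell indices
    edge_nodes: np.ndarray            # (m, 2) node ids
    edge_conductance: np.ndarray      # (m,)
    spec: object = None
    laplacian: sp.csr_matrix = field(default=None, repr=False)
    isolated_patches: list[int] = field(default_factory=list)

    def component_labels(self) -> np.ndarray:
        _, labels = connected_components(self.laplacian != 0, directed=False)
        return labels


@dataclass
class PairSolution:
    """Circuit solution for one source/target patch pair (I = V / R_eff)."""

    source_patch: int
    target_patch: int
    injected_current: float
    effective_resistance: float
    potentials: np.ndarray | None
    cell_current: Raster
    reachable: bool = True


@dataclass
class CurrentMap:
    """Cumulative per-cell current density over solved patch pairs."""

    raster: Raster
    n_pairs: int
    unreachable_pairs: list[tuple[int, int]] = field(default_factory=list)
    reff: pd.DataFrame | None = None


_OFFSETS_4 = [(0, 1, 1.0), (1, 0, 1.0)]
_OFFSETS_8 = _OFFSETS_4 + [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]


def build_graph(
    resistance: Raster, patch_labels: Raster, neighborhood: int = 8
) -> ConductanceGraph:
    """Conductance graph from a resistance raster and a patch label raster.

    Edge resistance between neighbouring cells a, b is (r_a + r_b) / 2,
    multiplied by sqrt(2) for diagonal links; conductance is its inverse.
    All cells sharing a patch label collapse into one supernode.
    """
    if neighborhood not in (4, 8):
        raise GraphError(f"neighborhood must be 4 or 8, got {neighborhood}")
    resistance.same_grid(patch_labels)
    spec = resistance.spec
    mask = resistance.mask & patch_labels.mask
    if not mask.any():
        raise EmptyGraphError("all cells are masked; no graph to build")
    if (resistance.values[mask] <= 0).any():
        raise GraphError("resistance values must be positive")

    nrows, ncols = spec.shape
    labels = patch_labels.values.astype(int)
    patch_ids = sorted(int(i) for i in np.unique(labels[mask]) if i > 0)

    # node numbering: free cells first, then one supernode per patch
    free = mask & (labels == 0)
    node_of_cell = np.full(nrows * ncols, -1, dtype=int)
    node_of_cell[free.ravel()] = np.arange(int(free.sum()))
    n_free = int(free.sum())
    patch_node = {pid: n_free + k for k, pid in enumerate(patch_ids)}
    flat_labels = labels.ravel()
    in_patch = (flat_labels > 0) & mask.ravel()
    if in_patch.any():
        lut = np.zeros(max(patch_ids) + 1, dtype=int)
        for pid, node in patch_node.items():
            lut[pid] = node
        node_of_cell[in_patch] = lut[flat_labels[in_patch]]
    n_nodes = n_free + len(patch_ids)

    offsets = _OFFSETS_4 if neighborhood == 4 else _OFFSETS_8
    res = resistance.values.astype(float)
    cells_a, cells_b, conds = [], [], []
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    for dr, dc, dist in offsets:
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols) & mask
        ok2 = np.zeros_like(ok)  # both endpoints must be valid
        ok2[ok] = mask[r2[ok], c2[ok]]
        ok = ok2
        a = (rows[ok] * ncols + cols[ok]).ravel()
        b = (r2[ok] * ncols + c2[ok]).ravel()
        edge_res = 0.5 * (res.ravel()[a] + res.ravel()[b]) * dist
        cells_a.append(a)
        cells_b.append(b)
        conds.append(1.0 / edge_res)
    cell_a = np.concatenate(cells_a)
    cell_b = np.concatenate(cells_b)
    g = np.concatenate(conds)

    ua, ub = node_of_cell[cell_a], node_of_cell[cell_b]
    keep = ua != ub  # drop intra-patch edges
    cell_a, cell_b, g, ua, ub = cell_a[keep], cell_b[keep], g[keep], ua[keep], ub[keep]

    # Laplacian with parallel edges merged by conductance summation
    rows_ = np.concatenate([ua, ub, ua, ub])
    cols_ = np.concatenate([ub, ua, ua, ub])
    vals_ = np.concatenate([-g, -g, g, g])
    lap = sp.coo_matrix((vals_, (rows_, cols_)), shape=(n_nodes, n_nodes)).tocsr()

    degree = np.asarray((lap != 0).sum(axis=1)).ravel() - 1
    isolated = [pid for pid, node in patch_node.items() if degree[node] <= 0]

    return ConductanceGraph(
        n_nodes=n_nodes,
        node_of_cell=node_of_cell,
        patch_node=patch_node,
        edge_cells=np.column_stack([cell_a, cell_b]),
        edge_nodes=np.column_stack([ua, ub]),
        edge_conductance=g,
        spec=spec,
        laplacian=lap,
        isolated_patches=isolated,
    )


def _cell_current_from_potentials(
    graph: ConductanceGraph, v: np.ndarray, terminals: dict[int, float]
) -> np.ndarray:
    """Per-cell current density: half the sum of incident absolute edge
    currents; patch cells display their supernode's throughput (terminals:
    the injected current)."""
    ua, ub = graph.edge_nodes[:, 0], graph.edge_nodes[:, 1]
    edge_current = graph.edge_conductance * np.abs(v[ua] - v[ub])
    spec = graph.spec
    flat = np.zeros(spec.nrows * spec.ncols)
    np.add.at(flat, graph.edge_cells[:, 0], 0.5 * edge_current)
    np.add.at(flat, graph.edge_cells[:, 1], 0.5 * edge_current)

    # supernode throughput painted onto every member cell
    node_throughput = np.zeros(graph.n_nodes)
    np.add.at(node_throughput, ua, 0.5 * edge_current)
    np.add.at(node_throughput, ub, 0.5 * edge_current)
    for node, inj in terminals.items():
        node_throughput[node] = inj
    for pid, node in graph.patch_node.items():
        members = np.flatnonzero(graph.node_of_cell == node)
        flat[members] = node_throughput[node]
    return flat.reshape(spec.shape)


def solve_pair(
    graph: ConductanceGraph,
    source: int,
    target: int,
    injected_current: float = 1.0,
    solver=None,
) -> PairSolution:
    """Solve one patch pair: unit current into the source supernode, target
    grounded. Disconnected pairs return R_eff = inf and a zero current map
    (flagged ``reachable=False``), not an exception.

    ``solver`` optionally reuses a prefactorized grounded Laplacian from
    :func:`accumulate_current` (valid only for one fixed target).
    """
    if source == target:
        raise GraphError("source and target patches must differ")
    for pid in (source, target):
        if pid not in graph.patch_node:
            raise GraphError(f"patch {pid} not present in graph")
    s, t = graph.patch_node[source], graph.patch_node[target]

    labels = graph.component_labels()
    spec = graph.spec
    if labels[s] != labels[t]:
        zero = Raster(np.zeros(spec.shape), spec)
        return PairSolution(source, target, injected_current, np.inf, None, zero,
                            reachable=False)

    if solver is None:
        solver = grounded_solver(graph, target)
    factor, keep = solver
    rhs = np.zeros(keep.size)
    rhs[np.searchsorted(keep, s)] = injected_current
    v = np.zeros(graph.n_nodes)
    v[keep] = factor(rhs)

    reff = (v[s] - v[t]) / injected_current
    cell_current = _cell_current_from_potentials(
        graph, v, {s: injected_current, t: injected_current}
    )
    # only the connected component of the terminals carries current
    return PairSolution(
        source_patch=source,
        target_patch=target,
        injected_current=injected_current,
        effective_resistance=float(reff),
        potentials=v,
        cell_current=Raster(cell_current, spec),
        reachable=True,
    )


def grounded_solver(graph: ConductanceGraph, target: int | None = None,
                    ground_node: int | None = None):
    """Prefactorize the Laplacian with the target grounded (removed),
    restricted to the target's connected component so disconnected side
    components cannot make the system singular.

    Returns ``(factor, keep)`` where ``keep`` holds the retained node ids.
    """
    if ground_node is None:
        ground_node = graph.patch_node[target]
    comp = graph.component_labels()
    keep = np.flatnonzero(
        (comp == comp[ground_node]) & (np.arange(graph.n_nodes) != ground_node)
    )
    lap_red = graph.laplacian[keep][:, keep].tocsc()
    return factorized(lap_red), keep


def kirchhoff_residual(graph: ConductanceGraph, solution: PairSolution) -> float:
    """Max net current at non-terminal nodes (should be ~0 by conservation)."""
    v = solution.potentials
    net = graph.laplacian @ v
    s = graph.patch_node[solution.source_patch]
    t = graph.patch_node[solution.target_patch]
    net[[s, t]] = 0.0
    return float(np.abs(net).max())


def accumulate_current(
    graph: ConductanceGraph,
    patches: PatchSet,
    pairs: list[tuple[int, int]] | None = None,
    sources_type: str | None = None,
) -> CurrentMap:
    """Cumulative current density over patch pairs.

    By default all unordered pairs of patches are solved (types I and II
    pooled); ``sources_type='I'`` restricts pairs to those with at least one
    type-I endpoint (the initial-migration scenario). Unreachable pairs
    contribute zero current and are reported, not raised.
    """
    ids = [p.id for p in patches if p.id in graph.patch_node]
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        if sources_type is not None:
            tmap = patches.types_by_id()
            pairs = [
                (a, b) for a, b in pairs
                if tmap[a] == sources_type or tmap[b] == sources_type
            ]
    if len(ids) < 2 or not pairs:
        raise GraphError("need at least 2 patches (and one pair) to accumulate current")

    spec = graph.spec
    total = np.zeros(spec.shape)
    unreachable: list[tuple[int, int]] = []
    reff = pd.DataFrame(np.inf, index=ids, columns=ids, dtype=float)
    np.fill_diagonal(reff.values, 0.0)

    # group pairs by target so each grounded factorization is reused
    by_target: dict[int, list[int]] = {}
    for a, b in pairs:
        by_target.setdefault(b, []).append(a)
    for target, sources_ in by_target.items():
        solver = None
        labels = graph.component_labels()
        t_node = graph.patch_node[target]
        for source in sources_:
            if labels[graph.patch_node[source]] != labels[t_node]:
                unreachable.append((source, target))
                continue
            if solver is None:
                solver = grounded_solver(graph, target)
            sol = solve_pair(graph, source, target, solver=solver)
            total += sol.cell_current.values
            reff.loc[source, target] = sol.effective_resistance
            reff.loc[target, source] = sol.effective_resistance
    return CurrentMap(
        raster=Raster(total, spec),
        n_pairs=len(pairs) - len(unreachable),
        unreachable_pairs=unreachable,
        reff=reff,
    )
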