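import numpy as np
import pytest

import ecocircuit as ec
from ecocircuit.circuit import GraphError, grounded_solver
from conftest import dense_reff, make_chain, random_instance


class TestBuildGraph:
    def test_uniform_chain_is_path_graph_with_reciprocal_conductance(self):
        res, labels = make_chain(5, r=20.0)
        graph = ec.build_graph(res, labels, neighborhood=4)
        assert graph.n_nodes == 5  # 3 free cells + 2 supernodes
        assert np.allclose(graph.edge_conductance, 1 / 20.0)
        assert len(graph.edge_conductance) == 4

    def test_edge_resistance_is_mean_of_cell_resistances(self):
        spec = ec.GridSpec(2, 2, 100.0)
        mask = np.zeros(spec.shape, dtype=bool)
        mask[0, :] = True
        values = np.array([[10.0, 30.0], [1.0, 1.0]])
        res = ec.Raster(values, spec, mask=mask.copy())
        labels = ec.Raster(np.zeros(spec.shape, dtype=int), spec, mask=mask.copy())
        graph = ec.build_graph(res, labels, neighborhood=4)
        assert np.allclose(graph.edge_conductance, [1 / 20.0])

    def test_diagonal_edges_scaled_by_sqrt2(self):
        spec = ec.GridSpec(2, 2, 100.0)
        res = ec.Raster(np.full(spec.shape, 10.0), spec)
        labels = ec.Raster(np.zeros(spec.shape, dtype=int), spec)
        graph = ec.build_graph(res, labels, neighborhood=8)
        conds = np.sort(graph.edge_conductance)
        assert np.allclose(conds[:2], 1 / (10.0 * np.sqrt(2)))
        assert np.allclose(conds[2:], 1 / 10.0)

    def test_patch_block_contracts_to_supernode_with_ring_degree(self):
        spec = ec.GridSpec(5, 5, 100.0)
        res = ec.Raster(np.full(spec.shape, 10.0), spec)
        labels = np.zeros(spec.shape, dtype=int)
        labels[1:4, 1:4] = 1
        graph = ec.build_graph(res, ec.Raster(labels, spec), neighborhood=8)
        assert graph.n_nodes == 16 + 1
        node = graph.patch_node[1]
        degree = graph.laplacian[node].getnnz() - 1  # minus the diagonal
        assert degree == 16  # every ring cell touches the 3x3 block

    def test_fully_masked_raster_is_an_error(self, spec10):
        mask = np.zeros(spec10.shape, dtype=bool)
        res = ec.Raster(np.ones(spec10.shape), spec10, mask=mask.copy())
        labels = ec.Raster(np.zeros(spec10.shape, dtype=int), spec10, mask=mask.copy())
        with pytest.raises(ec.circuit.EmptyGraphError):
            ec.build_graph(res, labels)


class TestSolvePair:
    def test_series_chain_closed_form(self):
        for n, r in [(5, 10.0), (12, 3.5)]:
            res, labels = make_chain(n, r=r)
            graph = ec.build_graph(res, labels, neighborhood=4)
            sol = ec.solve_pair(graph, 1, 2)
            assert sol.effective_resistance == pytest.approx((n - 1) * r, rel=1e-10)

    def test_two_parallel_channels_halve_resistance(self):
        r, L = 10.0, 6
        spec = ec.GridSpec(3, L + 2, 100.0)

        def build(two_channels: bool):
            mask = np.zeros(spec.shape, dtype=bool)
            mask[:, 0] = mask[:, L + 1] = True
            mask[0, :] = True
            if two_channels:
                mask[2, :] = True
            labels = np.zeros(spec.shape, dtype=int)
            labels[:, 0] = 1
            labels[:, L + 1] = 2
            res = ec.Raster(np.full(spec.shape, r), spec, mask=mask.copy())
            lab = ec.Raster(labels, spec, mask=mask.copy())
            graph = ec.build_graph(res, lab, neighborhood=4)
            return ec.solve_pair(graph, 1, 2).effective_resistance

        single = build(False)
        double = build(True)
        assert single == pytest.approx((L + 1) * r, rel=1e-10)
        assert double == pytest.approx(single / 2, rel=1e-10)

    def test_matches_dense_pseudoinverse_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            graph = random_instance(rng)
            sol = ec.solve_pair(graph, 1, 2)
            oracle = dense_reff(graph, 1, 2)
            assert sol.effective_resistance == pytest.approx(oracle, rel=1e-8)

    def test_kirchhoff_reciprocity_and_ohm(self):
        rng = np.random.default_rng(7)
        graph = random_instance(rng)
        fwd = ec.solve_pair(graph, 1, 2)
        rev = ec.solve_pair(graph, 2, 1)
        assert ec.kirchhoff_residual(graph, fwd) < 1e-8 * fwd.injected_current
        assert fwd.effective_resistance == pytest.approx(
            rev.effective_resistance, rel=1e-10
        )
        assert np.allclose(fwd.cell_current.values, rev.cell_current.values, atol=1e-9)
        # Ohm's law: injected current x R_eff equals the terminal voltage
        s = graph.patch_node[1]
        assert fwd.potentials[s] == pytest.approx(
            fwd.injected_current * fwd.effective_resistance, rel=1e-10
        )

    def test_rayleigh_monotonicity(self):
        """Raising one cell's resistance never lowers effective resistance."""
        rng = np.random.default_rng(42)
        spec = ec.GridSpec(10, 10, 100.0)
        values = np.exp(rng.normal(3, 1, size=spec.shape))
        labels = np.zeros(spec.shape, dtype=int)
        labels[0, 0], labels[9, 9] = 1, 2
        lab = ec.Raster(labels, spec)
        base = ec.solve_pair(
            ec.build_graph(ec.Raster(values, spec), lab), 1, 2
        ).effective_resistance
        for _ in range(5):
            r, c = rng.integers(0, 10, size=2)
            if labels[r, c]:
                continue
            bumped = values.copy()
            bumped[r, c] *= 10
            reff = ec.solve_pair(
                ec.build_graph(ec.Raster(bumped, spec), lab), 1, 2
            ).effective_resistance
            assert reff >= base - 1e-9

    def test_disconnected_pair_flagged_not_raised(self):
        spec = ec.GridSpec(4, 5, 100.0)
        mask = np.ones(spec.shape, dtype=bool)
        mask[:, 2] = False  # wall splits the grid
        labels = np.zeros(spec.shape, dtype=int)
        labels[1, 0], labels[1, 4] = 1, 2
        res = ec.Raster(np.full(spec.shape, 10.0), spec, mask=mask.copy())
        graph = ec.build_graph(res, ec.Raster(labels, spec, mask=mask.copy()))
        sol = ec.solve_pair(graph, 1, 2)
        assert not sol.reachable
        assert np.isinf(sol.effective_resistance)
        assert np.all(sol.cell_current.values == 0)

    def test_same_patch_and_missing_patch_rejected(self):
        res, labels = make_chain(4)
        graph = ec.build_graph(res, labels, neighborhood=4)
        with pytest.raises(GraphError):
            ec.solve_pair(graph, 1, 1)
        with pytest.raises(GraphError):
            ec.solve_pair(graph, 1, 99)


class TestAccumulate:
    @staticmethod
    def three_patch_graph():
        spec = ec.GridSpec(9, 9, 100.0)
        rng = np.random.default_rng(3)
        values = np.exp(rng.normal(3, 0.5, size=spec.shape))
        labels = np.zeros(spec.shape, dtype=int)
        labels[0, 0], labels[0, 8], labels[8, 4] = 1, 2, 3
        patches = None
        res = ec.Raster(values, spec)
        lab = ec.Raster(labels, spec)
        graph = ec.build_graph(res, lab)
        return graph, lab

    def test_two_patches_equal_single_pair_map(self):
        res, labels = make_chain(6)
        graph = ec.build_graph(res, labels, neighborhood=4)
        patches = _fake_patchset({1: "I", 2: "II"})
        cm = ec.accumulate_current(graph, patches)
        single = ec.solve_pair(graph, 1, 2)
        assert np.allclose(cm.raster.values, single.cell_current.values)
        assert cm.reff.loc[1, 2] == pytest.approx(single.effective_resistance)

    def test_three_patches_sum_cellwise(self):
        graph, _ = self.three_patch_graph()
        patches = _fake_patchset({1: "I", 2: "II", 3: "II"})
        cm = ec.accumulate_current(graph, patches)
        assert cm.n_pairs == 3
        manual = sum(
            ec.solve_pair(graph, a, b).cell_current.values
            for a, b in [(1, 2), (1, 3), (2, 3)]
        )
        assert np.allclose(cm.raster.values, manual, atol=1e-10)

    def test_sources_type_restriction(self):
        graph, _ = self.three_patch_graph()
        patches = _fake_patchset({1: "I", 2: "II", 3: "II"})
        cm = ec.accumulate_current(graph, patches, sources_type="I")
        assert cm.n_pairs == 2  # (1,2) and (1,3); the II-II pair is dropped

    def test_fewer_than_two_patches_rejected(self):
        res, labels = make_chain(4)
        lab_one = labels.copy_with(np.where(labels.values == 2, 0, labels.values))
        graph = ec.build_graph(res, lab_one, neighborhood=4)
        with pytest.raises(GraphError):
            ec.accumulate_current(graph, _fake_patchset({1: "I"}))

    def test_channel_scene_argmax_inside_channel(self, channel_solution):
        cur = channel_solution["current"].raster.values.copy()
        labels = channel_solution["labels"].values
        cur[labels > 0] = 0  # terminal throughput aside
        r, c = np.unravel_index(np.argmax(cur), cur.shape)
        assert channel_solution["scene"].channel_mask[r, c]


def _fake_patchset(types: dict[int, str]) -> ec.PatchSet:
    """PatchSet stand-in for graphs whose labels were painted directly."""
    from shapely.geometry import box

    patches = [
        ec.Patch(pid, t, box(pid * 10.0, 0.0, pid * 10.0 + 1.0, 1.0))
        for pid, t in types.items()
    ]
    return ec.PatchSet(patches)


def test_grounded_solver_reuse_matches_fresh_solve():
    res, labels = make_chain(8)
    graph = ec.build_graph(res, labels, neighborhood=4)
    solver = grounded_solver(graph, target=2)
    reused = ec.solve_pair(graph, 1, 2, solver=solver)
    fresh = ec.solve_pair(graph, 1, 2)
    assert reused.effective_resistance == pytest.approx(fresh.effective_resistance)
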