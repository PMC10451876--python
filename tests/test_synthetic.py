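import numpy as np
import pytest
from scipy import stats

import ecocircuit as ec
from ecocircuit.resistance import load_classification
from ecocircuit.synthetic import (
    ConfigurationError,
    PlacementError,
    SamplingError,
)

CFG = load_classification()


def group_of(codes):
    return np.vectorize(lambda c: CFG.group_of_code(int(c)))(codes)


class TestDem:
    def test_zero_relief_is_flat(self, spec10):
        dem = ec.generate_dem(spec10, relief=0, base_elevation=850, seed=1)
        assert np.all(dem.values == 850.0)

    def test_deterministic_and_bounded(self):
        spec = ec.GridSpec(50, 50, 100.0)
        a = ec.generate_dem(spec, relief=3000, base_elevation=700, smoothness=10, seed=42)
        b = ec.generate_dem(spec, relief=3000, base_elevation=700, smoothness=10, seed=42)
        assert np.array_equal(a.values, b.values)
        assert a.values.min() >= 700.0 and a.values.max() <= 3700.0
        # frozen regression values for this exact parameterization
        assert a.values.min() == pytest.approx(700.0)
        assert a.values.max() == pytest.approx(3700.0)
        assert a.values.mean() == pytest.approx(2158.918126561219, rel=1e-12)
        assert a.values[25, 25] == pytest.approx(1701.9082674722465, rel=1e-12)

    def test_smoothness_increases_autocorrelation(self):
        spec = ec.GridSpec(80, 80, 100.0)
        diffs = []
        for smooth in (1.5, 4.0, 12.0):
            dem = ec.generate_dem(spec, relief=1000, smoothness=smooth, seed=9)
            diffs.append(np.abs(np.diff(dem.values, axis=1)).mean())
        assert diffs[0] > diffs[1] > diffs[2]

    def test_invalid_parameters(self, spec10):
        with pytest.raises(ConfigurationError):
            ec.generate_dem(spec10, relief=-1)
        with pytest.raises(ConfigurationError):
            ec.generate_dem(spec10, smoothness=0.5)


class TestLanduse:
    def test_single_group_fills_grid(self, spec10):
        lu = ec.generate_landuse(spec10, class_weights={"forest_dry": 1.0}, seed=2)
        assert set(np.unique(group_of(lu.values))) == {"forest_dry"}

    def test_two_group_frequencies_track_weights(self):
        spec = ec.GridSpec(200, 200, 100.0)
        lu = ec.generate_landuse(
            spec, class_weights={"shrub_grass": 0.5, "forest_dry": 0.5}, seed=1
        )
        groups = group_of(lu.values)
        frac = (groups == "shrub_grass").mean()
        assert 0.45 <= frac <= 0.55

    def test_deterministic(self, spec10):
        a = ec.generate_landuse(spec10, seed=3)
        b = ec.generate_landuse(spec10, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_blobby_not_salt_and_pepper(self):
        """Group labels of orthogonal neighbours agree far more often than
        under an i.i.d. shuffle of the same composition."""
        spec = ec.GridSpec(100, 100, 100.0)
        lu = ec.generate_landuse(spec, seed=4)
        groups = group_of(lu.values)
        same = (groups[:, 1:] == groups[:, :-1]).mean()
        assert same > 0.9

    def test_bad_weights(self, spec10):
        with pytest.raises(ConfigurationError):
            ec.generate_landuse(spec10, class_weights={"nonsense": 1.0})
        with pytest.raises(ConfigurationError):
            ec.generate_landuse(spec10, class_weights={"forest_dry": 0.7})


class TestPatches:
    def test_counts_types_disjoint(self):
        spec = ec.GridSpec(60, 60, 100.0)
        ps = ec.generate_patches(spec, n_type1=2, n_type2=3, radius_cells=4, seed=11)
        assert len(ps) == 5
        assert len(ps.by_type("I")) == 2
        labels = ec.rasterize_patches(ps, spec)  # raises on overlap
        assert set(np.unique(labels.values)) == {0, 1, 2, 3, 4, 5}

    def test_infeasible_placement_raises(self):
        spec = ec.GridSpec(20, 20, 100.0)
        with pytest.raises(PlacementError):
            ec.generate_patches(spec, n_type1=10, n_type2=10, radius_cells=4, seed=0)


class TestWarningPoints:
    def test_degenerate_density_puts_all_points_in_one_cell(self, spec10):
        values = np.zeros(spec10.shape)
        values[4, 7] = 5.0
        pts = ec.generate_warning_points(
            ec.Raster(values, spec10), n=50, seed=0, jitter=False
        )
        x, y = spec10.cell_center(4, 7)
        assert np.allclose(pts, [float(x), float(y)])

    def test_uniform_density_is_consistent_with_uniform_sampling(self):
        spec = ec.GridSpec(5, 5, 100.0)
        current = ec.Raster(np.ones(spec.shape), spec)
        pts = ec.generate_warning_points(current, n=10000, seed=7, jitter=False)
        rows = ((spec.origin[1] - pts[:, 1]) / spec.cell_size).astype(int)
        cols = ((pts[:, 0] - spec.origin[0]) / spec.cell_size).astype(int)
        counts = np.bincount(rows * 5 + cols, minlength=25)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_deterministic_and_zero_map_errors(self, spec10):
        current = ec.Raster(np.random.default_rng(0).random(spec10.shape), spec10)
        a = ec.generate_warning_points(current, n=20, seed=5)
        b = ec.generate_warning_points(current, n=20, seed=5)
        assert np.array_equal(a, b)
        with pytest.raises(SamplingError):
            ec.generate_warning_points(ec.Raster(np.zeros(spec10.shape), spec10), n=5)


class TestScenes:
    def test_channel_scene_invariants(self, channel_solution):
        scene = channel_solution["scene"]
        groups = set(np.unique(group_of(scene.landuse.values)))
        assert groups == {
            "shrub_grass", "forest_dry", "swamp_beach_rural",
            "otherwood_paddy_rock", "urban_water",
        }
        assert scene.channel_mask.any()
        labels = channel_solution["labels"].values
        assert not (scene.channel_mask & (labels > 0)).any()
        # the planted channel is shrub (lowest resistance class)
        assert np.all(scene.landuse.values[scene.channel_mask] == 22)

    def test_mosaic_scene_spans_elevation_classes(self):
        scene = ec.mosaic_scene(seed=1, nrows=60, ncols=60, cell_size=500.0)
        z = scene.dem.values
        assert z.min() < 1000 and z.max() > 2000
        assert len(scene.patches) == 3
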