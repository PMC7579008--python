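import numpy as np
import pytest

from ashazard.synthetic import (
    ExceedanceModelSpec,
    LandscapeConfig,
    SamplingConfig,
    generate_landscape,
    paper_like_scenario,
    sample_arsenic_points,
    true_probability_raster,
)


def lag1_autocorrelation(field: np.ndarray) -> float:
    a = field[:, :-1].ravel()
    b = field[:, 1:].ravel()
    return float(np.corrcoef(a, b)[0, 1])


class TestGenerateLandscape:
    def test_seeded_determinism(self):
        cfg = LandscapeConfig(grid_shape=(40, 40), n_continuous=3, seed=9)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        for name in a.predictors:
            np.testing.assert_array_equal(a.predictors[name].data, b.predictors[name].data)
        np.testing.assert_array_equal(a.population.data, b.population.data)
        np.testing.assert_array_equal(a.urban.data, b.urban.data)

    def test_zero_correlation_length_gives_white_noise(self):
        cfg = LandscapeConfig(
            grid_shape=(200, 200), n_continuous=1, correlation_length=0.0, seed=1
        )
        field = generate_landscape(cfg).predictors["field_00"].data
        assert abs(lag1_autocorrelation(field)) < 0.05

    def test_long_correlation_length_gives_smooth_field(self):
        cfg = LandscapeConfig(
            grid_shape=(200, 200), n_continuous=1, correlation_length=20.0, seed=1
        )
        field = generate_landscape(cfg).predictors["field_00"].data
        assert lag1_autocorrelation(field) > 0.8

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(grid_shape=(0, 10))
        with pytest.raises(ValueError):
            LandscapeConfig(grid_shape=(10, 10), correlation_length=-1)
        with pytest.raises(ValueError):
            LandscapeConfig(grid_shape=(10, 10), categorical_levels=(1,))

    def test_stack_is_coregistered_with_expected_layers(self, small_landscape):
        grid = small_landscape.grid
        for raster in small_landscape.predictors.values():
            assert raster.spec == grid
        assert small_landscape.population.spec == grid
        assert small_landscape.urban.spec == grid
        assert np.all(small_landscape.population.data >= 0)
        assert set(np.unique(small_landscape.urban.data)) <= {0.0, 1.0}
        for name in small_landscape.categorical:
            codes = small_landscape.predictors[name].data
            assert np.array_equal(codes, np.round(codes))

    def test_region_polygons_partition_the_extent(self, small_landscape):
        from shapely.ops import unary_union

        grid = small_landscape.grid
        union = unary_union([r.polygon for r in small_landscape.regions])
        extent_area = (grid.lon_max - grid.lon0) * (grid.lat_max - grid.lat0)
        assert union.area == pytest.approx(extent_area)
        total = sum(r.polygon.area for r in small_landscape.regions)
        assert total == pytest.approx(extent_area)  # no overlaps


class TestSampleArsenicPoints:
    def test_seeded_determinism(self, small_landscape, small_mechanism):
        sampling = SamplingConfig(n_points=500, seed=3)
        a = sample_arsenic_points(small_landscape, small_mechanism, sampling)
        b = sample_arsenic_points(small_landscape, small_mechanism, sampling)
        assert a.equals(b)

    def test_points_fall_inside_the_grid(self, small_points, small_landscape):
        grid = small_landscape.grid
        assert grid.contains(small_points["lon"], small_points["lat"]).all()

    def test_large_negative_intercept_keeps_all_below_guideline(self, small_landscape):
        mech = ExceedanceModelSpec(intercept=-30.0)
        pts = sample_arsenic_points(
            small_landscape, mech, SamplingConfig(n_points=2000, seed=0)
        )
        assert (pts["as_ugL"] <= 10.0).all()

    def test_intercept_zero_gives_half_exceedance(self, small_landscape):
        mech = ExceedanceModelSpec(intercept=0.0)
        pts = sample_arsenic_points(
            small_landscape, mech, SamplingConfig(n_points=10_000, seed=4)
        )
        assert abs((pts["as_ugL"] > 10).mean() - 0.5) < 0.02

    def test_exceedance_calibrated_to_logistic_probabilities(
        self, small_landscape, small_mechanism
    ):
        # empirical rate must converge to the mean of the generating probabilities
        pts = sample_arsenic_points(
            small_landscape, small_mechanism, SamplingConfig(n_points=20_000, seed=8)
        )
        expected = pts["true_prob"].mean()
        observed = (pts["as_ugL"] > 10).mean()
        # three binomial standard errors
        se = np.sqrt(expected * (1 - expected) / len(pts))
        assert abs(observed - expected) < 3 * se + 1e-9

    def test_concentration_always_consistent_with_indicator(self, small_points):
        # indicator is recoverable from the concentration alone
        conc = small_points["as_ugL"].to_numpy()
        assert (conc > 0).all()

    def test_clustering_concentrates_points_in_few_cells(self):
        cfg = LandscapeConfig(grid_shape=(100, 100), n_continuous=1, seed=2)
        landscape = generate_landscape(cfg)
        mech = ExceedanceModelSpec()
        pts = sample_arsenic_points(
            landscape, mech, SamplingConfig(n_points=10_000, clustering_factor=50.0, seed=5)
        )
        row, col = landscape.grid.cell_of(pts["lon"].to_numpy(), pts["lat"].to_numpy())
        n_cells = len(set(zip(row, col)))
        assert n_cells < len(pts) / 10

    def test_unknown_predictor_name_rejected(self, small_landscape):
        mech = ExceedanceModelSpec(linear_coefficients={"no_such_field": 1.0})
        with pytest.raises(ValueError, match="no_such_field"):
            sample_arsenic_points(small_landscape, mech, SamplingConfig(n_points=10))

    def test_peaked_term_raises_probability_near_center(self, small_landscape):
        flat = ExceedanceModelSpec(intercept=-2.0)
        peaked = ExceedanceModelSpec(intercept=-2.0, peaked_terms={"field_00": (0.0, 0.5, 3.0)})
        p_flat = true_probability_raster(small_landscape, flat).data
        p_peak = true_probability_raster(small_landscape, peaked).data
        z = small_landscape.predictors["field_00"].data
        near = np.abs(z) < 0.2
        far = np.abs(z) > 2.0
        assert (p_peak[near] - p_flat[near]).mean() > 10 * (p_peak[far] - p_flat[far]).mean()


class TestPaperLikeScenario:
    def test_invalid_sampling_configs_rejected(self):
        with pytest.raises(ValueError):
            SamplingConfig(n_points=0)
        with pytest.raises(ValueError):
            SamplingConfig(n_points=10, hotspot_fraction=1.5)

    def test_scenario_is_frozen_and_reproducible(self):
        a = paper_like_scenario(seed=0)
        b = paper_like_scenario(seed=0)
        assert a == b
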