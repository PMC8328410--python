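import numpy as np
import pytest

from resiligrid import (
    MetricsConfig,
    PeriodPartition,
    compute_pixel_metrics,
    ndvi_reduction,
    rain_reduction,
    resilience,
    resistance,
)
from resiligrid.metrics import REASON_CODES

from conftest import make_cube


class TestScalarOperations:
    @pytest.mark.parametrize(
        "p_normal,p_dry,expected",
        [(300.0, 270.0, 0.10), (200.0, 200.0, 0.0), (250.0, 275.0, -0.10)],
    )
    def test_rain_reduction(self, p_normal, p_dry, expected):
        assert rain_reduction(p_normal, p_dry) == pytest.approx(expected)

    def test_rain_reduction_requires_positive_normal(self):
        with pytest.raises(ValueError, match="p_normal > 0"):
            rain_reduction(0.0, 10.0)

    @pytest.mark.parametrize(
        "n_normal,n_dry,expected",
        [(0.40, 0.38, 0.05), (0.30, 0.30, 0.0), (0.25, 0.26, -0.04)],
    )
    def test_ndvi_reduction(self, n_normal, n_dry, expected):
        assert ndvi_reduction(n_normal, n_dry) == pytest.approx(expected)

    def test_ndvi_reduction_flags_bare_ground_as_nan(self):
        assert np.isnan(ndvi_reduction(0.0, 0.1))
        assert np.isnan(ndvi_reduction(-0.05, 0.1))

    @pytest.mark.parametrize(
        "rain_red,ndvi_red,expected",
        [(0.10, 0.05, 2.0), (0.08, 0.08, 1.0), (0.06, 0.01, 6.0)],
    )
    def test_resistance(self, rain_red, ndvi_red, expected):
        assert resistance(rain_red, ndvi_red) == pytest.approx(expected)

    def test_resistance_contract_on_filtered_pixels(self):
        with pytest.raises(ValueError, match="filtered-out"):
            resistance(-0.02, 0.05)
        with pytest.raises(ValueError, match="filtered-out"):
            resistance(0.05, 0.0)

    @pytest.mark.parametrize(
        "n_post,n_normal,n_dry,denom,expected",
        [
            (0.30, 0.30, 0.25, "normal", 1.0),
            (0.24, 0.30, 0.25, "normal", 0.8),
            (0.33, 0.40, 0.30, "dry", 1.1),
        ],
    )
    def test_resilience(self, n_post, n_normal, n_dry, denom, expected):
        assert resilience(n_post, n_normal, n_dry, denom) == pytest.approx(expected)

    def test_resilience_nonpositive_denominator_is_nan(self):
        assert np.isnan(resilience(0.3, 0.0, 0.2, "normal"))
        assert np.isnan(resilience(0.3, 0.4, 0.0, "dry"))


def three_period_cubes(p_vals, n_vals):
    """1-year periods; period means equal the layer values exactly."""
    precip = make_cube(np.asarray(p_vals, dtype=float))
    # recovery precip layer unused by the metrics; reuse the dry layer
    ndvi = make_cube(np.asarray(n_vals, dtype=float))
    part = PeriodPartition([2000], [2001], [2002])
    return precip, ndvi, part


class TestComputePixelMetrics:
    def test_single_pixel_composition(self):
        precip, ndvi, part = three_period_cubes(
            [[[300.0]], [[270.0]], [[280.0]]],
            [[[0.40]], [[0.38]], [[0.40]]],
        )
        pm = compute_pixel_metrics(precip, ndvi, part)
        assert pm.rain_reduction[0, 0] == pytest.approx(0.10)
        assert pm.ndvi_reduction[0, 0] == pytest.approx(0.05)
        assert pm.resistance[0, 0] == pytest.approx(2.0)
        assert pm.resilience[0, 0] == pytest.approx(1.0)
        assert pm.valid[0, 0]

    def test_below_min_ndvi_reduction_excluded(self):
        precip, ndvi, part = three_period_cubes(
            [[[300.0]], [[270.0]], [[280.0]]],
            [[[0.400]], [[0.398]], [[0.40]]],  # reduction 0.005 < 1%
        )
        pm = compute_pixel_metrics(precip, ndvi, part)
        assert not pm.valid[0, 0]
        assert pm.exclusion_reason[0, 0] == REASON_CODES["ndvi_reduction_below_min"]
        assert np.isnan(pm.resistance[0, 0])

    def test_no_rain_reduction_excluded(self):
        precip, ndvi, part = three_period_cubes(
            [[[300.0]], [[310.0]], [[280.0]]],
            [[[0.40]], [[0.30]], [[0.40]]],
        )
        pm = compute_pixel_metrics(precip, ndvi, part)
        assert pm.exclusion_reason[0, 0] == REASON_CODES["no_rain_reduction"]

    def test_composition_matches_scalar_ops_bitwise(self, rng):
        shape = (1, 12, 12)
        p_n = 50 + 450 * rng.random(shape)
        p_d = p_n * (0.6 + 0.3 * rng.random(shape))
        n_n = 0.1 + 0.6 * rng.random(shape)
        n_d = n_n * (0.8 + 0.18 * rng.random(shape))
        n_p = n_n * (0.7 + 0.4 * rng.random(shape))
        precip = make_cube(np.concatenate([p_n, p_d, p_d]))
        ndvi = make_cube(np.concatenate([n_n, n_d, n_p]))
        part = PeriodPartition([2000], [2001], [2002])
        pm = compute_pixel_metrics(precip, ndvi, part)
        rr = rain_reduction(p_n[0], p_d[0])
        nr = ndvi_reduction(n_n[0], n_d[0])
        np.testing.assert_array_equal(pm.rain_reduction, rr)
        np.testing.assert_array_equal(pm.ndvi_reduction, nr)
        v = pm.valid
        np.testing.assert_array_equal(pm.resistance[v], resistance(rr[v], nr[v]))
        np.testing.assert_array_equal(
            pm.resilience, resilience(n_p[0], n_n[0], n_d[0], "normal")
        )

    def test_scale_invariance_of_ndvi_ratios(self, rng):
        shape = (1, 8, 8)
        p_n = 200 + 100 * rng.random(shape)
        p_d = p_n * 0.9
        n_n = 0.2 + 0.4 * rng.random(shape)
        n_d = n_n * (0.85 + 0.1 * rng.random(shape))
        n_p = n_n * (0.9 + 0.2 * rng.random(shape))
        part = PeriodPartition([2000], [2001], [2002])
        precip = make_cube(np.concatenate([p_n, p_d, p_d]))
        base = compute_pixel_metrics(
            precip, make_cube(np.concatenate([n_n, n_d, n_p])), part
        )
        c = 0.37
        scaled = compute_pixel_metrics(
            precip, make_cube(np.concatenate([c * n_n, c * n_d, c * n_p])), part
        )
        np.testing.assert_allclose(
            scaled.ndvi_reduction, base.ndvi_reduction, rtol=1e-12
        )
        np.testing.assert_allclose(
            scaled.resistance[base.valid], base.resistance[base.valid], rtol=1e-12
        )
        np.testing.assert_allclose(scaled.resilience, base.resilience, rtol=1e-12)
        np.testing.assert_array_equal(scaled.valid, base.valid)

    def test_filter_soundness(self, rng):
        shape = (1, 20, 20)
        p_n = 50 + 450 * rng.random(shape)
        p_d = p_n * (0.8 + 0.4 * rng.random(shape))   # some wetter dry periods
        n_n = 0.05 + 0.6 * rng.random(shape)
        n_d = n_n * (0.9 + 0.2 * rng.random(shape))   # some increases
        precip = make_cube(np.concatenate([p_n, p_d, p_d]))
        ndvi = make_cube(np.concatenate([n_n, n_d, n_d]))
        part = PeriodPartition([2000], [2001], [2002])
        pm = compute_pixel_metrics(precip, ndvi, part)
        v = pm.valid
        assert np.all(pm.rain_reduction[v] > 0)
        assert np.all(pm.ndvi_reduction[v] >= pm.config.min_ndvi_reduction)
        assert np.all(np.isfinite(pm.resistance[v]))
        assert np.all(pm.resistance[v] > 0)

    def test_nonvegetated_pixels_are_nodata(self):
        precip, ndvi, part = three_period_cubes(
            [[[300.0]], [[270.0]], [[280.0]]],
            [[[0.0]], [[0.0]], [[0.0]]],
        )
        pm = compute_pixel_metrics(precip, ndvi, part)
        assert pm.exclusion_reason[0, 0] == REASON_CODES["nodata"]

    def test_grid_mismatch_is_an_error(self, rng):
        precip = make_cube(np.ones((3, 4, 4)))
        ndvi = make_cube(np.full((3, 5, 5), 0.4))
        part = PeriodPartition([2000], [2001], [2002])
        with pytest.raises(ValueError, match="co-registered"):
            compute_pixel_metrics(precip, ndvi, part)

    def test_dataframe_round_trips_reason_names(self):
        precip, ndvi, part = three_period_cubes(
            [[[300.0]], [[270.0]], [[280.0]]],
            [[[0.40]], [[0.38]], [[0.40]]],
        )
        pm = compute_pixel_metrics(precip, ndvi, part)
        df = pm.to_dataframe()
        assert df.loc[0, "exclusion_reason"] == "none"
        assert set(df.columns) >= {
            "map_mm", "rain_reduction", "ndvi_reduction", "resistance",
            "resilience", "resilience_normal", "resilience_dry", "valid",
        }
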