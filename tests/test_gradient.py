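import numpy as np
import pandas as pd
import pytest

from resiligrid import (
    bin_by_map,
    fit_candidates,
    peak_of_fit,
    select_fit,
    subset_by_rain_reduction,
)
from resiligrid.gradient import BinnedProfile


def pixels_frame(map_mm, y, valid=None, rain_reduction=None):
    n = len(map_mm)
    return pd.DataFrame(
        {
            "map_mm": map_mm,
            "resp": y,
            "valid": valid if valid is not None else [True] * n,
            "rain_reduction": rain_reduction if rain_reduction is not None else [0.1] * n,
        }
    )


def profile_from(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return BinnedProfile(
        bin_lo=x - 25, bin_hi=x + 25, bin_mid=x,
        n_pixels=np.full(x.size, 100), mean_y=y,
        sd_y=np.full(x.size, 0.1), response="resp", width=50.0,
        n_total=int(100 * x.size),
    )


class TestBinning:
    def test_hand_binning(self):
        prof = bin_by_map(
            pixels_frame([60.0, 70.0, 120.0], [1.0, 2.0, 3.0]), "resp",
            width=50, n_min=1,
        )
        np.testing.assert_array_equal(prof.bin_lo, [50.0, 100.0])
        np.testing.assert_allclose(prof.mean_y, [1.5, 3.0])
        np.testing.assert_array_equal(prof.n_pixels, [2, 1])

    def test_span_100_to_499_gives_8_bins(self, rng):
        map_mm = rng.uniform(100, 499, size=400)
        prof = bin_by_map(pixels_frame(map_mm, map_mm), "resp", width=50, n_min=1)
        assert prof.n_bins == 8

    def test_boundary_value_in_upper_bin(self):
        prof = bin_by_map(
            pixels_frame([150.0, 150.0], [1.0, 1.0]), "resp", width=50, n_min=1
        )
        np.testing.assert_array_equal(prof.bin_lo, [150.0])
        np.testing.assert_array_equal(prof.bin_hi, [200.0])

    def test_binning_conserves_pixels(self, rng):
        map_mm = rng.uniform(40, 500, size=1000)
        prof = bin_by_map(pixels_frame(map_mm, map_mm), "resp", width=50, n_min=1)
        assert prof.n_pixels.sum() == 1000 == prof.n_total

    def test_n_min_drops_sparse_bins(self):
        prof = bin_by_map(
            pixels_frame([60.0] * 20 + [120.0], list(range(21))), "resp",
            width=50, n_min=10,
        )
        np.testing.assert_array_equal(prof.bin_lo, [50.0])

    def test_invalid_pixels_ignored(self):
        prof = bin_by_map(
            pixels_frame([60.0, 70.0], [1.0, 99.0], valid=[True, False]),
            "resp", width=50, n_min=1,
        )
        np.testing.assert_allclose(prof.mean_y, [1.0])

    def test_zero_valid_pixels_is_an_error(self):
        with pytest.raises(ValueError, match="zero valid"):
            bin_by_map(
                pixels_frame([60.0], [1.0], valid=[False]), "resp", n_min=1
            )


class TestSubset:
    def test_closed_interval_endpoints(self):
        df = pixels_frame(
            [1, 2, 3, 4, 5], [0] * 5,
            rain_reduction=[0.04, 0.05, 0.07, 0.10, 0.11],
        )
        assert len(subset_by_rain_reduction(df, 0.05, 0.10)) == 3

    def test_full_interval_is_identity_on_valid(self):
        df = pixels_frame(
            [1, 2, 3], [0] * 3, valid=[True, False, True],
            rain_reduction=[0.2, 0.3, 0.4],
        )
        assert len(subset_by_rain_reduction(df, 0.0, 1.0)) == 2

    def test_empty_subset_is_legal_and_fails_downstream(self):
        df = pixels_frame([1.0], [0.0], rain_reduction=[0.5])
        sub = subset_by_rain_reduction(df, 0.05, 0.10)
        assert len(sub) == 0
        with pytest.raises(ValueError, match="zero valid"):
            bin_by_map(sub, "resp", n_min=1)

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            subset_by_rain_reduction(pixels_frame([1.0], [0.0]), 0.2, 0.1)


class TestFitCandidates:
    def test_exact_linear_selected_with_r2_one(self):
        x = np.arange(25.0, 475.0, 50.0)
        fits = fit_candidates(profile_from(x, 1 + 0.002 * x))
        sel = select_fit(fits)
        assert sel.family == "linear"
        assert sel.r2 == pytest.approx(1.0, abs=1e-9)
        assert sel.p_value <= 0.05

    def test_exact_quadratic_beats_linear_and_ties_break_down(self):
        x = np.arange(25.0, 500.0, 50.0)  # symmetric about 250
        y = -((x - 250.0) ** 2) / 1e4 + 5.0
        fits = fit_candidates(profile_from(x, y))
        sel = select_fit(fits)
        assert sel.family == "quadratic"
        assert sel.r2 == pytest.approx(1.0, abs=1e-9)
        families = {f.family for f in fits}
        assert "cubic" in families  # cubic also exact but has more parameters

    def test_exact_exponential_recovered(self):
        # gate the line out so the candidate comparison itself is probed
        x = np.arange(25.0, 500.0, 50.0)
        y = 2.0 * np.exp(-0.004 * x)
        fits = fit_candidates(profile_from(x, y), p_gate=1e-15)
        sel = select_fit(fits)
        assert sel.family == "exponential"
        assert sel.r2 == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(sel.coefficients, [2.0, -0.004], rtol=1e-4)

    def test_insufficient_bins_is_an_error(self):
        x = np.array([25.0, 75.0, 125.0, 175.0])
        with pytest.raises(ValueError, match="insufficient bins"):
            fit_candidates(profile_from(x, x))

    def test_ci_band_contains_fitted_curve(self, rng):
        x = np.arange(25.0, 500.0, 50.0)
        y = 1 + 0.004 * x + 0.1 * rng.standard_normal(x.size)
        for fit in fit_candidates(profile_from(x, y), p_gate=1e-12, seed=0):
            fitted = fit.predict(fit.ci_x)
            assert np.all(fit.ci_lo <= fitted + 1e-9)
            assert np.all(fit.ci_hi >= fitted - 1e-9)

    def test_r2_invariant_to_affine_map_rescaling(self, rng):
        x = np.arange(25.0, 500.0, 50.0)
        y = 0.5 + 0.01 * x - 2e-5 * x ** 2 + 0.05 * rng.standard_normal(x.size)
        fits_a = fit_candidates(profile_from(x, y), p_gate=1e-12)
        fits_b = fit_candidates(profile_from(2.0 * x + 30.0, y), p_gate=1e-12)
        for fa, fb in zip(fits_a, fits_b):
            if fa.family == "exponential":
                continue
            assert fa.r2 == pytest.approx(fb.r2, abs=1e-8)

    def test_selection_is_unique(self, rng):
        x = np.arange(25.0, 500.0, 50.0)
        y = rng.random(x.size)
        fits = fit_candidates(profile_from(x, y))
        assert sum(f.selected for f in fits) == 1


class TestPeakOfFit:
    def test_quadratic_vertex(self):
        x = np.arange(25.0, 500.0, 50.0)
        y = -((x - 250.0) ** 2) / 1e4 + 5.0
        sel = select_fit(fit_candidates(profile_from(x, y)))
        peak = peak_of_fit(sel, (0.0, 500.0))
        assert peak.map_mm == pytest.approx(250.0, abs=1e-6)
        assert not peak.on_boundary

    def test_monotone_cubic_flagged_as_boundary(self):
        from resiligrid.gradient import GradientFit
        fit = GradientFit(
            family="cubic", coefficients=np.array([0.0, 1.0, 1e-4, 1e-7]),
            r2=1.0, p_value=0.01,
        )
        peak = peak_of_fit(fit, (0.0, 500.0))
        assert peak.map_mm == pytest.approx(500.0)
        assert peak.on_boundary

    def test_cubic_interior_peak_matches_dense_grid(self):
        from resiligrid.gradient import GradientFit
        coef = np.array([0.0, 3.0e-2, -1.0e-4, 8.0e-8])  # interior maximum
        fit = GradientFit(family="cubic", coefficients=coef, r2=1.0, p_value=0.01)
        peak = peak_of_fit(fit, (0.0, 500.0))
        xs = np.linspace(0.0, 500.0, 2_000_001)
        dense = xs[np.argmax(fit.predict(xs))]
        assert peak.map_mm == pytest.approx(dense, abs=1e-3)
        roots = np.polynomial.polynomial.polyroots(
            np.polynomial.polynomial.polyder(coef)
        )
        closed_form = min(
            (float(r.real) for r in roots if 0 < r.real < 500),
            key=lambda r: -fit.predict(np.array([r])),
        )
        assert peak.map_mm == pytest.approx(closed_form, abs=1e-6)

    def test_linear_has_no_interior_peak(self):
        from resiligrid.gradient import GradientFit
        fit = GradientFit(
            family="linear", coefficients=np.array([1.0, 0.1]), r2=1.0,
            p_value=0.01,
        )
        with pytest.raises(ValueError, match="no interior peak"):
            peak_of_fit(fit, (0.0, 500.0))
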