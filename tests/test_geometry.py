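"""Lumen delineation, profile cleaning, and radius-model fitting."""

import numpy as np
import pytest
from scipy import ndimage

from vaflow.geometry import (CrossSection, GeometryError, RadiusProfile,
                             clean_radius_profile, fit_linear_taper,
                             fit_three_phase, fwhm_delineate,
                             sample_at_stations)


def _disk_image(radius_px, size=41, lumen=200.0, background=0.0,
                edge_px=1.0):
    rr, cc = np.indices((size, size))
    c = (size - 1) / 2.0
    d = np.hypot(rr - c, cc - c)
    cover = np.clip((radius_px - d) / edge_px + 0.5, 0.0, 1.0)
    return background + (lumen - background) * cover


class TestFWHM:
    def test_ideal_disk_radius(self):
        sec = CrossSection(_disk_image(8.0), pixel_size=1.0)
        assert fwhm_delineate(sec) == pytest.approx(8.0, abs=0.5)

    def test_half_level_between_lumen_and_background(self):
        """With lumen 100 and background 20 the boundary sits at intensity
        60; a linear edge ramp is crossed at its midpoint within 0.1 px."""
        sec = CrossSection(_disk_image(10.0, size=51, lumen=100.0,
                                       background=20.0, edge_px=3.0),
                           pixel_size=1.0)
        r, widths = fwhm_delineate(sec, n_rays=16, return_half_widths=True)
        # axis-aligned rays see the exact analytic ramp crossing
        axis_widths = widths[[0, 8, 16, 24]]
        assert np.allclose(axis_widths, 10.0, atol=0.1)

    def test_rotation_invariance(self):
        img = _disk_image(9.0, size=61, edge_px=2.0)
        sec = CrossSection(img, pixel_size=1.0)
        rot = ndimage.rotate(img, 17.0, reshape=False, order=1, cval=0.0)
        sec_rot = CrossSection(rot, pixel_size=1.0)
        assert fwhm_delineate(sec_rot) == pytest.approx(
            fwhm_delineate(sec), rel=0.01)

    def test_pixel_size_scales_radius(self):
        sec = CrossSection(_disk_image(6.0), pixel_size=0.78)
        assert fwhm_delineate(sec) == pytest.approx(6.0 * 0.78, abs=0.5 * 0.78)

    def test_flat_image_raises(self):
        with pytest.raises(GeometryError):
            fwhm_delineate(CrossSection(np.zeros((31, 31)), pixel_size=1.0))


class TestCleaner:
    def test_single_spike_removed_rest_untouched(self):
        r = np.full(50, 2.0)
        r[20] = 6.0
        out = clean_radius_profile(RadiusProfile(np.arange(50.0), r))
        assert not out.valid[20]
        assert out.valid.sum() == 49
        assert np.array_equal(out.radii, r)

    def test_idempotent_on_clean_profile(self):
        rng = np.random.default_rng(5)
        r = 2.0 + 0.01 * rng.standard_normal(60)
        prof = RadiusProfile(np.arange(60.0), r)
        once = clean_radius_profile(prof)
        twice = clean_radius_profile(once)
        assert np.array_equal(once.valid, twice.valid)

    def test_constant_profile_untouched(self):
        out = clean_radius_profile(RadiusProfile(np.arange(20.0),
                                                 np.full(20, 1.5)))
        assert out.valid.all()

    def test_requires_ten_samples(self):
        with pytest.raises(GeometryError):
            clean_radius_profile(RadiusProfile(np.arange(5.0),
                                               np.full(5, 1.0)))


class TestLinearTaper:
    def test_exact_on_linear_and_constant_data(self):
        s = np.arange(0.0, 100.0)
        fit = fit_linear_taper(RadiusProfile(s, 2.0 - 0.01 * s))
        assert fit.r_begin == pytest.approx(2.0, abs=1e-9)
        assert fit.r_end == pytest.approx(2.0 - 0.99, abs=1e-9)
        flat = fit_linear_taper(RadiusProfile(s, np.full(100, 1.5)))
        assert flat.r_begin == pytest.approx(1.5)
        assert flat.r_end == pytest.approx(1.5)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        s = np.arange(0.0, 80.0)
        r = np.abs(1.8 - 0.004 * s + 0.05 * rng.standard_normal(80))
        fit = fit_linear_taper(RadiusProfile(s, r))
        x = np.column_stack([np.ones_like(s), s])
        beta = np.linalg.solve(x.T @ x, x.T @ r)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)

    def test_degenerate_raises(self):
        with pytest.raises(GeometryError):
            fit_linear_taper(RadiusProfile(np.array([0.0, 1.0]),
                                           np.array([1.0, 1.0]),
                                           np.array([True, False])))


def _three_phase_data(s, t1, t2, b0=4.0, m1=-0.01, m2=-0.03, m3=-0.005):
    return (b0 + m1 * s + (m2 - m1) * np.clip(s - t1, 0, None)
            + (m3 - m2) * np.clip(s - t2, 0, None))


def _naive_three_phase(s, r, min_segment=3, constant_first=False):
    """Exhaustive per-pair least-squares oracle (independent of the
    suffix-sum fast path)."""
    best = None
    for i1 in range(min_segment - 1, s.size - min_segment):
        for i2 in range(i1 + min_segment, s.size - min_segment + 1):
            cols = [np.ones_like(s), np.clip(s - s[i1], 0, None),
                    np.clip(s - s[i2], 0, None)]
            if not constant_first:
                cols.insert(1, s)
            x = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(x, r, rcond=None)
            sse = float(np.sum((r - x @ beta) ** 2))
            if best is None or sse < best[0] - 1e-12:
                best = (sse, s[i1], s[i2])
    return best


class TestThreePhase:
    def test_noiseless_exact_recovery(self):
        s = np.arange(0.0, 150.0)
        fit = fit_three_phase(RadiusProfile(s, _three_phase_data(s, 40, 95)))
        assert (fit.t1, fit.t2) == (40.0, 95.0)
        assert fit.sse == pytest.approx(0.0, abs=1e-8)
        assert fit.slopes == pytest.approx((-0.01, -0.03, -0.005), abs=1e-8)

    def test_single_line_gives_zero_sse_equal_slopes(self):
        s = np.arange(0.0, 60.0)
        fit = fit_three_phase(RadiusProfile(s, 3.0 - 0.002 * s))
        assert fit.sse == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.slopes, -0.002, atol=1e-8)

    def test_constant_first_recovers_flat_regime_mean(self):
        s = np.arange(0.0, 120.0)
        r = np.where(s < 50, 3.5,
                     np.where(s < 90, 3.5 - 0.02 * (s - 50),
                              2.7 - 0.004 * (s - 90)))
        fit = fit_three_phase(RadiusProfile(s, r), constant_first=True)
        assert fit.coef[0] == pytest.approx(np.mean(r[s < 50]), abs=1e-9)
        assert fit.slopes[0] == 0.0

    @pytest.mark.parametrize("constant_first", [False, True])
    def test_matches_exhaustive_search_oracle(self, constant_first):
        rng = np.random.default_rng(11)
        s = np.arange(0.0, 90.0)
        r = np.abs(_three_phase_data(s, 30, 60)
                   * (1 + 0.05 * rng.standard_normal(s.size)))
        fit = fit_three_phase(RadiusProfile(s, r),
                              constant_first=constant_first)
        sse_o, t1_o, t2_o = _naive_three_phase(s, r,
                                               constant_first=constant_first)
        assert fit.sse == pytest.approx(sse_o, rel=1e-8)
        assert (fit.t1, fit.t2) == (t1_o, t2_o)

    def test_sse_not_worse_than_linear(self):
        rng = np.random.default_rng(3)
        s = np.arange(0.0, 100.0)
        r = np.abs(2.5 - 0.005 * s + 0.1 * rng.standard_normal(100))
        assert fit_three_phase(RadiusProfile(s, r)).sse <= \
            fit_linear_taper(RadiusProfile(s, r)).sse + 1e-9

    def test_breakpoint_recovery_under_noise(self):
        """Median absolute transition-point error stays below 2 samples over
        100 noisy replicates (sigma = 5% of radius)."""
        rng = np.random.default_rng(42)
        s = np.arange(0.0, 150.0)
        # flat proximal regime, strong mid taper, gentle distal taper --
        # the shape of a subclavian/axillary/brachial chain
        truth = _three_phase_data(s, 45, 100, b0=4.0, m1=0.0, m2=-0.035,
                                  m3=-0.005)
        errs = []
        for _ in range(100):
            r = np.abs(truth * (1 + 0.05 * rng.standard_normal(s.size)))
            fit = fit_three_phase(RadiusProfile(s, r))
            errs.append(abs(fit.t1 - 45.0))
            errs.append(abs(fit.t2 - 100.0))
        assert np.median(errs) < 2.0

    def test_insufficient_span_raises(self):
        with pytest.raises(GeometryError):
            fit_three_phase(RadiusProfile(np.arange(6.0), np.full(6, 2.0)))


class TestSampleAtStations:
    def test_continuity_and_midpoint(self):
        s = np.arange(0.0, 120.0)
        fit = fit_three_phase(RadiusProfile(s, _three_phase_data(s, 40, 80)))
        left = sample_at_stations(fit, [40.0 - 1e-9])[0]
        right = sample_at_stations(fit, [40.0 + 1e-9])[0]
        assert left == pytest.approx(right, abs=1e-6)
        lin = fit_linear_taper(RadiusProfile(s, 2.0 - 0.01 * s))
        mid = sample_at_stations(lin, [59.5])[0]
        assert mid == pytest.approx((lin.r_begin + lin.r_end) / 2.0)

    def test_matches_piecewise_formula_oracle(self):
        s = np.arange(0.0, 150.0)
        fit = fit_three_phase(RadiusProfile(s, _three_phase_data(s, 40, 95)))
        rng = np.random.default_rng(9)
        stations = rng.uniform(0.0, 149.0, size=10)
        expected = _three_phase_data(stations, 40, 95)
        assert np.allclose(sample_at_stations(fit, stations), expected,
                           atol=1e-7)

    def test_station_out_of_range_raises(self):
        s = np.arange(0.0, 50.0)
        lin = fit_linear_taper(RadiusProfile(s, 2.0 - 0.001 * s))
        with pytest.raises(GeometryError):
            sample_at_stations(lin, [60.0])
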