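"""Baseline correction: trimming, endpoint search, baseline model, gridding."""

import numpy as np
import pytest

from tlbtools import (
    EndpointParams,
    ExclusionRegion,
    GridSpec,
    ThermogramError,
    ThermogramProfile,
    UnprocessableProfileError,
    auto_baseline,
    find_stable_window,
    fit_baseline,
    multiple_auto_baseline,
    select_endpoint,
    trim_profile,
)
from tlbtools.baseline import _smooth_spline

from conftest import URINE, gaussian, make_profile


class TestTrim:
    def test_range_filter(self):
        p = make_profile(start=20, end=95, fn=lambda t: 0.1 * t)
        out = trim_profile(p)
        assert out.temperatures[0] >= 45 and out.temperatures[-1] <= 90

    def test_heater_activation_spike_removed(self):
        p = make_profile(fn=lambda t: 0.01 * t)
        v = p.heat_capacity.copy()
        d = np.abs(np.diff(v))
        mad = np.median(np.abs(d - np.median(d)))
        v[0] += 100 * max(mad, 1e-6) + 1.0  # far beyond the robust fence
        spiked = ThermogramProfile("s", p.temperatures, v)
        out = trim_profile(spiked)
        assert out.n_points == p.n_points - 1
        np.testing.assert_array_equal(out.heat_capacity, v[1:])

    def test_post_transition_spike_removed_symmetrically(self):
        p = make_profile(fn=lambda t: 0.01 * t)
        v = p.heat_capacity.copy()
        v[-1] -= 50.0
        out = trim_profile(ThermogramProfile("s", p.temperatures, v))
        assert out.n_points == p.n_points - 1

    def test_clean_profile_unchanged(self, urine_high):
        p, _ = urine_high
        out = trim_profile(p)
        np.testing.assert_array_equal(out.heat_capacity, p.heat_capacity)

    def test_too_short_after_trim_raises(self):
        p = make_profile(start=58, end=62, ppd=10)  # 41 points
        with pytest.raises(UnprocessableProfileError):
            trim_profile(p)


class TestStableWindow:
    def brute_force(self, temps, values, w):
        """Independent oracle: explicit loop over every window."""
        spline = _smooth_spline(np.asarray(temps), np.asarray(values))
        resid = values - spline(temps)
        sds = [np.std(resid[k:k + w], ddof=1)
               for k in range(len(values) - w + 1)]
        return int(np.argmin(sds)), np.asarray(sds)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_segments(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(45, 60, 400))
        t += np.arange(400) * 1e-9  # ensure strictly increasing
        v = 0.01 * t + rng.normal(0, 0.01, 400)
        start, sds = find_stable_window(t, v, 90)
        bf_start, bf_sds = self.brute_force(t, v, 90)
        np.testing.assert_allclose(sds, bf_sds, rtol=1e-12)
        assert start == bf_start

    def test_selects_injected_low_noise_plateau(self):
        rng = np.random.default_rng(11)
        t = np.linspace(45, 60, 300)
        sigma = np.full(300, 0.1)
        sigma[120:230] = 0.001  # quiet plateau
        v = rng.normal(0, 1.0, 300) * sigma
        start, _ = find_stable_window(t, v, 90)
        assert 120 <= start and start + 90 <= 230

    def test_single_window_when_n_equals_w(self):
        t = np.linspace(45, 50, 90)
        start, sds = find_stable_window(t, np.sin(t), 90)
        assert start == 0 and sds.size == 1

    def test_segment_shorter_than_window_raises(self):
        t = np.linspace(45, 50, 50)
        with pytest.raises(ThermogramError):
            find_stable_window(t, np.sin(t), 90)

    def test_tie_break_prefers_exclusion_side(self):
        t = np.linspace(45, 50, 30)
        v = np.zeros(30)  # all-zero residuals: every window ties at SD 0
        start_pre, _ = find_stable_window(t, v, 10, side="pre")
        start_post, _ = find_stable_window(t, v, 10, side="post")
        assert start_pre == 20  # nearest the exclusion region from below
        assert start_post == 0  # nearest from above


class TestSelectEndpoint:
    temps = np.linspace(45, 60, 150)

    def test_pre_innermost_is_highest_temperature(self):
        assert select_endpoint(self.temps, 10, 90, "pre", "innermost") == \
            self.temps[99]

    def test_post_innermost_is_lowest_temperature(self):
        assert select_endpoint(self.temps, 10, 90, "post", "innermost") == \
            self.temps[10]

    def test_midpoint_floor_arithmetic(self):
        assert select_endpoint(self.temps, 7, 5, "pre", "midpoint") == \
            self.temps[9]

    def test_window_outside_segment_raises(self):
        with pytest.raises(ThermogramError):
            select_endpoint(self.temps, 100, 90, "pre", "innermost")

    @pytest.mark.parametrize("start,w", [(0, 90), (30, 50), (5, 7)])
    def test_method_ordering_is_monotone(self, start, w):
        pre = [select_endpoint(self.temps, start, w, "pre", m)
               for m in ("outermost", "midpoint", "innermost")]
        assert pre[0] <= pre[1] <= pre[2]
        post = [select_endpoint(self.temps, start, w, "post", m)
                for m in ("outermost", "midpoint", "innermost")]
        assert post[0] >= post[1] >= post[2]


class TestFitBaseline:
    def test_linear_segments_give_analytic_chord(self):
        # pre and post segments on different lines; peak in between
        t = np.linspace(45, 90, 451)
        v = np.where(t <= 60, 2.0 + 0.1 * t, 1.0 + 0.05 * t)
        v = v + gaussian(70, 2, 5.0)(t) * ((t > 60) & (t < 80))
        p = ThermogramProfile("chord", t, v)
        fit = fit_baseline(p, 60.0, 80.0)
        y_low, y_high = 2.0 + 0.1 * 60, 1.0 + 0.05 * 80
        mid = (t > 60) & (t < 80)
        chord = y_low + (y_high - y_low) * (t[mid] - 60) / 20.0
        np.testing.assert_allclose(fit.baseline_values[mid], chord, atol=1e-6)

    def test_baseline_only_profile_reproduced(self):
        p = make_profile(fn=lambda t: 3.0 - 0.02 * t)
        fit = fit_baseline(p, 60.0, 80.0)
        rng = np.ptp(p.heat_capacity)
        assert np.max(np.abs(fit.baseline_values - p.heat_capacity)) < 1e-6 * rng

    def test_continuity_at_endpoints(self, urine_high):
        p, _ = urine_high
        fit = fit_baseline(p, 58.0, 82.0)
        i_low = np.searchsorted(p.temperatures, 58.0)
        # value just inside the connector equals the linear interpolant
        # anchored at the spline endpoint values (continuity by construction)
        assert np.all(np.isfinite(fit.baseline_values))
        assert fit.lower_endpoint == 58.0 and fit.upper_endpoint == 82.0
        assert i_low > 0

    def test_inverted_endpoints_raise(self, urine_high):
        p, _ = urine_high
        with pytest.raises(ThermogramError):
            fit_baseline(p, 80.0, 60.0)

    def test_too_few_points_names_the_side(self):
        p = make_profile(fn=lambda t: 0.1 * t)
        with pytest.raises(ThermogramError, match="pre-transition"):
            fit_baseline(p, 45.2, 80.0)
        with pytest.raises(ThermogramError, match="post-transition"):
            fit_baseline(p, 60.0, 89.8)


class TestAutoBaseline:
    def test_noiseless_gaussian_recovered(self):
        p = make_profile(fn=gaussian(70, 2, 1.0))
        g = auto_baseline(p, URINE)
        grid = g.grid_temperatures
        at = lambda T: g.corrected_values[np.argmin(np.abs(grid - T))]
        assert abs(at(70.0) - 1.0) < 0.01
        assert abs(at(50.0)) < 0.01 and abs(at(85.0)) < 0.01

    def test_linear_drift_removed(self):
        peak = gaussian(70, 2, 1.0)
        flat = auto_baseline(make_profile(fn=peak), URINE)
        drifted = auto_baseline(
            make_profile(fn=lambda t: peak(t) + 3.0 - 0.04 * t), URINE)
        np.testing.assert_allclose(drifted.corrected_values,
                                   flat.corrected_values, atol=0.02)

    def test_profile_without_baseline_segments_raises(self):
        p = make_profile(start=62, end=78, ppd=15)
        with pytest.raises(UnprocessableProfileError):
            auto_baseline(p, URINE)

    def test_grid_conformance(self, urine_high):
        p, _ = urine_high
        g = auto_baseline(p, URINE)
        assert g.grid_temperatures.size == 451
        assert g.grid_temperatures[0] == 45.0
        assert g.grid_temperatures[-1] == 90.0
        steps = np.diff(g.grid_temperatures)
        np.testing.assert_allclose(steps, 0.1, atol=1e-9)

    def test_no_extrapolation_outside_observed_span(self):
        p = make_profile(start=50, end=88, ppd=15, fn=gaussian(70, 2, 1.0))
        g = auto_baseline(p, URINE)
        grid = g.grid_temperatures
        assert np.isnan(g.corrected_values[grid < 50]).all()
        assert np.isnan(g.corrected_values[grid > 88]).all()
        inside = (grid >= 50) & (grid <= 88)
        assert np.isfinite(g.corrected_values[inside]).all()

    def test_endpoints_bracket_exclusion_region(self, urine_high):
        p, _ = urine_high
        for method in ("innermost", "midpoint", "outermost"):
            g = auto_baseline(p, URINE, EndpointParams(method=method))
            fit = g.fit_metadata
            assert fit.lower_endpoint <= 60.0
            assert fit.upper_endpoint >= 80.0

    def test_deterministic_bit_identical(self, urine_high):
        p, _ = urine_high
        g1 = auto_baseline(p, URINE)
        g2 = auto_baseline(p, URINE)
        np.testing.assert_array_equal(g1.corrected_values, g2.corrected_values)
        assert g1.fit_metadata.lower_endpoint == g2.fit_metadata.lower_endpoint

    def test_sd_traces_recorded(self, urine_high):
        p, _ = urine_high
        g = auto_baseline(p, URINE)
        fit = g.fit_metadata
        assert fit.pre_window_sds is not None and fit.pre_window_sds.size > 1
        assert np.all(fit.pre_window_sds >= 0)


class TestBatchBaseline:
    def test_failure_isolation(self, urine_high):
        good, _ = urine_high
        profiles = [good,
                    make_profile("short", start=58, end=62, ppd=10),
                    ThermogramProfile("ok2", good.temperatures,
                                      good.heat_capacity + 1.0)]
        gridded, failures = multiple_auto_baseline(profiles, URINE)
        assert [g.sample_id for g in gridded] == [good.sample_id, "ok2"]
        assert len(failures) == 1 and failures[0].sample_id == "short"

    def test_empty_input(self):
        gridded, failures = multiple_auto_baseline([], URINE)
        assert gridded == [] and failures == []

    def test_batch_equals_elementwise(self, urine_high):
        p, _ = urine_high
        q = ThermogramProfile("q", p.temperatures, p.heat_capacity * 2)
        batch, _ = multiple_auto_baseline([p, q], URINE)
        single = [auto_baseline(x, URINE) for x in (p, q)]
        for b, s in zip(batch, single):
            np.testing.assert_array_equal(b.corrected_values,
                                          s.corrected_values)

    def test_per_sample_override(self, urine_high):
        p, _ = urine_high
        wide = ExclusionRegion(55.0, 80.0)
        batch, _ = multiple_auto_baseline(
            [p], URINE, overrides={p.sample_id: wide})
        assert batch[0].fit_metadata.lower_endpoint <= 55.0
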