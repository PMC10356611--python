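"""ΔF/F pipeline and event-aligned statistics."""

import numpy as np
import pytest

from eggsearch import (
    DffTrace,
    FluorescenceRecording,
    boxcar,
    compute_dff,
    cross_correlate,
    resample_previous_neighbour,
    slope_to_threshold,
    stim_response_bins,
    triggered_average,
)


def _rec(f_cell, f_bg=None, dt=0.667, t0=0.3):
    n = len(f_cell)
    t = t0 + np.arange(n) * dt
    bg = np.full(n, 30.0) if f_bg is None else np.asarray(f_bg, float)
    return FluorescenceRecording(t, np.asarray(f_cell, float), bg)


class TestComputeDff:
    def test_constant_channels_give_zero(self):
        rec = _rec(np.full(400, 130.0))
        out = compute_dff(rec)
        finite = out.dff[np.isfinite(out.dff)]
        assert len(finite)
        np.testing.assert_allclose(finite, 0.0, atol=1e-12)

    def test_cell_equal_background_is_degenerate(self):
        f = np.full(400, 30.0)
        with pytest.raises(ValueError, match="F0 non-positive"):
            compute_dff(_rec(f, f))

    def test_ramp_matches_windowed_mean_oracle(self):
        n = 900
        dt = 0.667
        t = np.arange(n) * dt
        sig = 100.0 * (1.0 + np.clip((t - 300) / 100, 0, 0.35))
        rec = _rec(sig + 30.0, np.full(n, 30.0), dt=dt, t0=0.0)
        out = compute_dff(rec, window_s=1200.0)
        f_act = rec.F_cell - rec.F_background
        oracle = np.empty(n)
        for i in range(n):
            w = np.abs(rec.volume_t - rec.volume_t[i]) <= 600.0
            f0 = f_act[w].mean()
            oracle[i] = (f_act[i] - f0) / f0
        grid, oracle_g = resample_previous_neighbour(oracle, rec.volume_t, 10.0)
        sel = np.isfinite(out.dff) & np.isfinite(oracle_g)
        np.testing.assert_allclose(out.dff[sel], oracle_g[sel], atol=1e-9)

    def test_gain_and_offset_invariance(self):
        # multiplying both channels by a common gain and adding a common
        # offset to both leaves the background-subtracted ratio unchanged
        rng = np.random.default_rng(0)
        cell = 120 + 5 * rng.standard_normal(500)
        bg = np.full(500, 20.0)
        a = compute_dff(_rec(cell, bg))
        c = compute_dff(_rec(3.0 * cell + 7.0, 3.0 * bg + 7.0))
        sel = np.isfinite(a.dff) & np.isfinite(c.dff)
        np.testing.assert_allclose(a.dff[sel], c.dff[sel], atol=1e-10)

    def test_stimulation_blanking_masks_f0_and_flags_samples(self):
        n = 600
        dt = 0.667
        f = np.full(n, 130.0)
        t = np.arange(n) * dt
        onset = 100.0
        stim_sel = (t >= onset) & (t < onset + 105.0)
        f[stim_sel] += 200.0  # stimulation transient
        rec = _rec(f, dt=dt, t0=0.0)
        out = compute_dff(rec, stim_schedule=[onset])
        assert out.stim_mask.any()
        unmasked = np.isfinite(out.dff) & ~out.stim_mask
        np.testing.assert_allclose(out.dff[unmasked], 0.0, atol=1e-12)

    def test_running_mean_keeps_dff_near_zero_on_noise(self):
        rng = np.random.default_rng(42)
        n = 2400  # ~27 min at 0.667 s
        f = 130.0 + 3.0 * rng.standard_normal(n)
        out = compute_dff(_rec(f, dt=0.667, t0=0.0))
        mid = out.dff[np.isfinite(out.dff)]
        assert abs(np.mean(mid)) < 0.02


class TestResample:
    def test_previous_neighbour_examples(self):
        grid, vals = resample_previous_neighbour([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        i = int(np.searchsorted(grid, 1.5))
        assert vals[i] == 2.0  # 1.5 s takes the 1 s sample

    def test_grid_before_first_sample_is_nan(self):
        grid, vals = resample_previous_neighbour([5.0, 6.0], [0.33, 1.0])
        assert np.isnan(vals[grid < 0.33]).all()
        assert vals[-1] == 6.0

    def test_random_timestamps_match_linear_scan(self):
        rng = np.random.default_rng(1)
        ts = np.sort(rng.uniform(0, 30, 40))
        ts += np.arange(40) * 1e-6  # ensure strictly increasing
        vals = rng.standard_normal(40)
        grid, out = resample_previous_neighbour(vals, ts, 10.0)
        for g, o in zip(grid, out):
            prior = np.flatnonzero(ts <= g + 1e-12)
            expected = vals[prior[-1]] if len(prior) else np.nan
            assert (np.isnan(o) and np.isnan(expected)) or o == expected

    def test_empty_series(self):
        grid, out = resample_previous_neighbour([], [])
        assert len(grid) == 0 and len(out) == 0


class TestBoxcar:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.3)
        np.testing.assert_allclose(boxcar(x, 2.0), x)

    def test_unit_impulse_spreads_evenly(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = boxcar(x, 0.5, dt=0.1)  # 5-sample window
        np.testing.assert_allclose(out[8:13], 0.2)

    def test_interior_nans_dropped_from_window(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(60)
        x[[10, 11, 30]] = np.nan
        out = boxcar(x, 0.5, dt=0.1)
        n = 5
        half = n // 2
        for i in range(len(x)):
            w = x[max(0, i - half) : min(len(x) - 1, i + half) + 1]
            w = w[np.isfinite(w)]
            expected = w.mean() if len(w) else np.nan
            assert (np.isnan(out[i]) and np.isnan(expected)) or out[i] == pytest.approx(expected)


class TestTriggeredAverage:
    def test_constant_trace_gives_flat_mean_zero_sem(self):
        t = np.arange(0, 100, 0.1)
        ens = triggered_average(t, np.full_like(t, 2.0), [20.0, 50.0, 80.0], 5.0)
        np.testing.assert_allclose(ens.mean, 2.0)
        np.testing.assert_allclose(ens.sem, 0.0)
        assert (ens.n == 3).all()

    def test_return_event_truncates_contribution(self):
        t = np.arange(0, 200, 0.1)
        trace = np.ones_like(t)
        ens = triggered_average(t, trace, [100.0], 40.0, exclusion_events=[120.0])
        rel = ens.rel_t
        assert np.isfinite(ens.traces[0][rel < 19.9]).all()
        assert np.isnan(ens.traces[0][rel >= 20.0]).all()
        # ensemble n never increases with |relative time| once exclusions apply
        post = ens.n[rel >= 0]
        assert (np.diff(post.astype(int)) <= 0).all()

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 120, 0.1)
        trace = rng.standard_normal(len(t))
        events = rng.uniform(5, 115, 7)
        excl = np.sort(rng.uniform(5, 120, 5))
        ens = triggered_average(t, trace, events, 8.0, exclusion_events=excl)
        nw = int(round(8.0 / 0.1))
        for k, ev in enumerate(events):
            i0 = int(np.searchsorted(t, ev + 1e-12, side="right") - 1)
            for j, off in enumerate(range(-nw, nw + 1)):
                idx = i0 + off
                val = trace[idx] if 0 <= idx < len(t) else np.nan
                nxt = [x for x in excl if x > ev]
                if nxt and 0 <= idx < len(t) and t[idx] >= nxt[0] - 1e-12:
                    val = np.nan
                got = ens.traces[k, j]
                assert (np.isnan(got) and np.isnan(val)) or got == val
        finite_cols = ens.n > 1
        mean_oracle = np.nanmean(ens.traces, axis=0)
        sem_oracle = np.nanstd(ens.traces, axis=0, ddof=1) / np.sqrt(ens.n)
        np.testing.assert_allclose(ens.mean[finite_cols], mean_oracle[finite_cols], atol=1e-12)
        np.testing.assert_allclose(ens.sem[finite_cols], sem_oracle[finite_cols], atol=1e-12)

    def test_no_usable_events_raises(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(ValueError):
            triggered_average(t, np.zeros_like(t), [50.0], 2.0)


class TestCrossCorrelate:
    def test_self_correlation_peaks_at_zero_with_value_one(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 60, 0.1)
        a = rng.standard_normal(len(t))
        lags, corr = cross_correlate(t, a, a, max_lag_s=5.0)
        assert corr[np.flatnonzero(lags == 0)[0]] == pytest.approx(1.0)
        assert np.nanargmax(corr) == np.flatnonzero(lags == 0)[0]

    def test_known_shift_recovers_documented_sign(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 120, 0.1)
        a = np.convolve(rng.standard_normal(len(t)), np.ones(20) / 20, mode="same")
        shift = 30  # b delayed by 3 s: b(t) = a(t - 3)
        b = np.roll(a, shift)
        b[:shift] = np.nan
        lags, corr = cross_correlate(t, a, b, max_lag_s=6.0)
        peak_lag = lags[np.nanargmax(corr)]
        assert peak_lag == pytest.approx(3.0)  # peak where b(t + L) aligns with a(t)

    def test_common_latent_signal_peaks_at_zero_lag(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 300, 0.1)
        latent = np.convolve(rng.standard_normal(len(t)), np.ones(50) / 50, mode="same")
        a = latent + 0.3 * rng.standard_normal(len(t))
        b = latent + 0.3 * rng.standard_normal(len(t))
        lags, corr = cross_correlate(t, a, b, max_lag_s=10.0)
        assert abs(lags[np.nanargmax(corr)]) <= 0.2

    def test_insufficient_overlap_raises(self):
        t = np.arange(0, 2, 0.1)
        a = np.full(len(t), np.nan)
        with pytest.raises(ValueError):
            cross_correlate(t, a, a)


class TestSlopeToThreshold:
    def _trace(self, y, t0=0.0):
        t = t0 + np.arange(len(y)) * 0.1
        return DffTrace(t, np.asarray(y, float))

    def test_linear_rise_gives_amplitude_over_time(self):
        t = np.arange(0, 100, 0.1)
        # min -0.1 at 40 s, crossing 0 at 51.8 s, 0.35 at endpoint 96.7 s
        y = np.full_like(t, 0.05)
        seg = (t >= 40.0)
        y[seg] = -0.1 + (t[seg] - 40.0) * (0.45 / 56.7)
        y[t < 40.0] = np.linspace(0.05, -0.1, np.sum(t < 40.0))
        dff = DffTrace(t, y)
        slope = slope_to_threshold(dff, 10.0, 100.0, smooth_s=0.1, end_offset_s=3.3)
        # amplitude 0.35 climbed over ~44 s from the zero-crossing
        assert slope == pytest.approx(0.35 / 44.1, rel=0.03)

    def test_flat_zero_after_minimum_gives_zero_slope(self):
        t = np.arange(0, 60, 0.1)
        y = np.zeros_like(t)
        dff = DffTrace(t, y)
        assert slope_to_threshold(dff, 5.0, 50.0, smooth_s=0.5) == pytest.approx(0.0)

    def test_never_reaching_zero_is_flagged_nan(self):
        t = np.arange(0, 60, 0.1)
        dff = DffTrace(t, np.full_like(t, -0.2))
        assert np.isnan(slope_to_threshold(dff, 5.0, 50.0))

    def test_high_drift_cohort_has_steeper_slopes(self):
        """Rise slope discriminates strong from weak drive (20 vs 20 traces)."""
        from eggsearch import binary_group_ranksum
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        slopes = {"high": [], "low": []}
        for name, r in (("high", 0.004), ("low", 0.001)):
            for _ in range(20):
                t = np.arange(0, 240, 0.1)
                y = np.full_like(t, -0.1)
                rise = t >= 60.0
                y[rise] = -0.1 + r * (t[rise] - 60.0)
                y = y + 0.01 * rng.standard_normal(len(t))
                dff = DffTrace(t, y)
                s = slope_to_threshold(dff, 30.0, 230.0)
                if np.isfinite(s):
                    slopes[name].append(s)
        assert np.mean(slopes["high"]) > np.mean(slopes["low"])
        p = mannwhitneyu(slopes["high"], slopes["low"], alternative="two-sided").pvalue
        assert p < 0.05


class TestStimResponseBins:
    def _dff_with_peaks(self, peaks, spacing=60.0):
        t = np.arange(0, spacing * (len(peaks) + 1), 0.1)
        y = np.zeros_like(t)
        onsets = []
        for i, pk in enumerate(peaks):
            onset = spacing * (i + 0.5)
            onsets.append(onset)
            sel = (t >= onset + 1.0) & (t <= onset + 3.0)
            y[sel] = pk
        return DffTrace(t, y), onsets

    @pytest.mark.parametrize(
        "peak,expected_bin", [(0.01, 1), (0.60, 7), (0.30, 4), (0.02, 2), (0.52, 7)]
    )
    def test_bin_assignment_edges(self, peak, expected_bin):
        dff, onsets = self._dff_with_peaks([peak])
        out = stim_response_bins(dff, onsets)
        assert out.loc[0, "bin"] == expected_bin

    def test_behaviour_delta_is_post_minus_pre(self):
        dff, onsets = self._dff_with_peaks([0.3])
        t = dff.t
        beh = np.where(t >= onsets[0] + 1.0, 4.0, 1.0)
        out = stim_response_bins(dff, onsets, behaviour={"angle": beh})
        assert out.loc[0, "delta_angle"] == pytest.approx(4.0 - 1.0)

    def test_stimulation_near_recording_end_skipped(self):
        dff, onsets = self._dff_with_peaks([0.3])
        out = stim_response_bins(dff, [dff.t[-1] - 1.0])
        assert len(out) == 0
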