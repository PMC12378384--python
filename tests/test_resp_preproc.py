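"""Saturation repair, resampling, alignment, and peak detection, checked
against brute-force and analytic oracles."""

import numpy as np
import pytest

from breathturn import synthio
from breathturn.physio_io import SessionTimeline
from breathturn.resp_preproc import (
    RespirationTrace,
    align_to_session,
    detect_peaks,
    detect_saturation,
    interpolate_gaps,
    moving_average,
    preprocess,
    resample_to_ms,
)


def _jaccard(a, b):
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0, hi - lo)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


class TestMovingAverage:
    def test_constant_signal_unchanged(self):
        trace = RespirationTrace(samples=np.full(100, 3.5), rate=200.0)
        np.testing.assert_allclose(moving_average(trace).samples, 3.5)

    def test_toy_ramp_matches_brute_force_windows(self):
        # even window of 4 is centered on the leading sample: [i-2, i+1]
        x = np.arange(10, dtype=float)
        trace = RespirationTrace(samples=x, rate=1.0)
        out = moving_average(trace, window_bins=4).samples
        for i in range(10):
            lo, hi = max(0, i - 2), min(10, i + 2)
            assert out[i] == pytest.approx(np.mean(x[lo:hi]))

    def test_window_longer_than_signal_is_error(self):
        trace = RespirationTrace(samples=np.zeros(10), rate=1.0)
        with pytest.raises(ValueError):
            moving_average(trace, window_bins=11)

    def test_50_bins_at_200hz_spans_250ms(self):
        assert 50 / 200.0 == 0.25


class TestDetectSaturation:
    def test_monotone_ramp_has_no_plateaus(self):
        trace = RespirationTrace(samples=np.linspace(0, 1, 1000), rate=200.0)
        assert detect_saturation(trace, deriv_tol=0.0) == []

    def test_recovers_clipped_runs_with_high_jaccard(self, sine_trace):
        clipped, true_runs = synthio.apply_saturation(sine_trace, -0.9, 0.9)
        smoothed = moving_average(clipped, 50)
        found = detect_saturation(smoothed, expand_bins=25)
        assert len(found) == len(true_runs)
        for t, f in zip(true_runs, found):
            assert _jaccard(t, f) >= 0.9

    def test_midrange_flat_run_not_flagged(self):
        # a breathing pause at mid amplitude is not a saturation plateau
        rate = 200.0
        t = np.arange(int(20 * rate)) / rate
        x = np.sin(2 * np.pi * t / 3.0)
        x[2000:2100] = x[2000]  # flat run at whatever level the sine has there
        trace = RespirationTrace(samples=x, rate=rate)
        found = detect_saturation(trace, deriv_tol=0.0, min_run=10)
        for start, stop in found:
            assert not (start < 2100 and stop > 2000) or abs(x[2000]) > 0.7

    def test_min_run_filters_short_plateaus(self):
        x = np.linspace(0, 1, 500)
        x[200:205] = x[200]
        trace = RespirationTrace(samples=x, rate=200.0)
        assert detect_saturation(trace, deriv_tol=0.0, min_run=10) == []


class TestInterpolateGaps:
    def test_empty_interval_list_is_identity(self, sine_trace):
        out = interpolate_gaps(sine_trace, [])
        np.testing.assert_array_equal(out.samples, sine_trace.samples)

    def test_spline_repair_beats_clipping_and_restores_peak_times(self, sine_trace):
        clipped, runs = synthio.apply_saturation(sine_trace, -0.9, 0.9)
        repaired = interpolate_gaps(clipped, runs)
        truth = sine_trace.samples
        rmse_clip = np.sqrt(np.mean((clipped.samples - truth) ** 2))
        rmse_rep = np.sqrt(np.mean((repaired.samples - truth) ** 2))
        assert rmse_rep < rmse_clip
        # repaired maxima within 25 ms of the analytic peak times 0.75 + 3k
        peaks = detect_peaks(resample_to_ms(repaired), min_separation=1.0)
        for p in peaks:
            true_t = 0.75 + 3.0 * round((p.time - 0.75) / 3.0)
            assert abs(p.time - true_t) < 0.025

    def test_no_discontinuity_at_gap_borders(self, sine_trace):
        clipped, runs = synthio.apply_saturation(sine_trace, -0.9, 0.9)
        repaired = interpolate_gaps(clipped, runs)
        jumps = np.abs(np.diff(repaired.samples))
        assert jumps.max() < 0.05  # << sample-to-sample slope of the sine

    def test_edge_interval_held_not_extrapolated(self, caplog):
        import logging

        x = np.linspace(0, 1, 200)
        trace = RespirationTrace(samples=x.copy(), rate=100.0)
        with caplog.at_level(logging.WARNING, logger="breathturn.resp_preproc"):
            out = interpolate_gaps(trace, [(0, 10)])
        assert np.all(out.samples[:10] == x[10])
        assert any("edge" in r.message for r in caplog.records)

    def test_oversized_gap_rejected(self, sine_trace):
        n = sine_trace.n
        with pytest.raises(ValueError):
            interpolate_gaps(sine_trace, [(0, int(0.6 * n))])


class TestResampleToMs:
    def test_constant_stays_constant(self):
        trace = RespirationTrace(samples=np.full(100, 2.0), rate=200.0)
        out = resample_to_ms(trace)
        assert out.rate == 1000.0
        np.testing.assert_allclose(out.samples, 2.0)

    def test_linear_ramp_is_exact(self):
        t = np.arange(100) / 200.0
        trace = RespirationTrace(samples=3.0 * t, rate=200.0)
        out = resample_to_ms(trace)
        np.testing.assert_allclose(out.samples, 3.0 * out.times, atol=1e-12)

    def test_slow_sine_error_below_1e3(self):
        rate = 200.0
        t = np.arange(int(10 * rate) + 1) / rate
        trace = RespirationTrace(samples=np.sin(2 * np.pi * 1.0 * t), rate=rate)
        out = resample_to_ms(trace)
        err = np.abs(out.samples - np.sin(2 * np.pi * out.times))
        assert err.max() < 1e-3

    def test_endpoints_preserved_to_1ms(self, sine_trace):
        out = resample_to_ms(sine_trace)
        assert abs(out.times[0] - sine_trace.times[0]) < 1e-3
        assert abs(out.times[-1] - sine_trace.times[-1]) < 1e-3


class TestAlignToSession:
    def test_equal_durations_give_zero_origin(self):
        timeline = SessionTimeline(session_duration=463.925, n_volumes=385, tr=1.205)
        n = int(463.925 * 200) + 1
        trace = RespirationTrace(samples=np.zeros(n), rate=200.0)
        assert align_to_session(trace, timeline).origin == pytest.approx(0.0)

    def test_longer_trace_gets_negative_origin(self):
        timeline = SessionTimeline(session_duration=463.925)
        n = int(465.0 * 200) + 1
        trace = RespirationTrace(samples=np.zeros(n), rate=200.0)
        out = align_to_session(trace, timeline)
        assert out.origin == pytest.approx(-1.075)
        assert out.times[-1] == pytest.approx(463.925)


class TestDetectPeaks:
    def test_sine_peaks_at_analytic_argmax(self, sine_trace):
        peaks = detect_peaks(resample_to_ms(sine_trace))
        assert len(peaks) == 10
        for k, p in enumerate(peaks):
            assert abs(p.time - (0.75 + 3.0 * k)) <= 0.002

    def test_monotone_signal_has_no_peaks(self):
        trace = RespirationTrace(samples=np.linspace(0, 1, 5000), rate=200.0)
        assert detect_peaks(trace) == []

    def test_recovers_ground_truth_peaks(self, conversation):
        bp = synthio.BreathCycleParams(noise_sd=0.005)
        trace, truth = synthio.generate_respiration(
            conversation, breath_params=bp, seed=21
        )
        _, peaks, _ = preprocess(trace)
        det = np.array([p.time for p in peaks])
        hits = sum(
            1 for t in truth.true_peak_times if np.min(np.abs(det - t)) < 0.05
        )
        assert hits / len(truth.true_peak_times) >= 0.98


class TestChainProperties:
    def test_preprocess_is_deterministic(self, respiration):
        trace, _ = respiration
        _, p1, _ = preprocess(trace)
        _, p2, _ = preprocess(trace)
        assert [(p.time, p.amplitude) for p in p1] == [
            (p.time, p.amplitude) for p in p2
        ]

    def test_repair_of_unclipped_trace_is_identity(self, respiration):
        trace, _ = respiration
        smoothed = moving_average(trace, 50)
        intervals = detect_saturation(smoothed, expand_bins=25)
        repaired = interpolate_gaps(trace, intervals)
        np.testing.assert_array_equal(repaired.samples, trace.samples)

    def test_peak_count_invariant_under_rescaling(self, respiration):
        trace, _ = respiration
        _, p1, _ = preprocess(trace)
        scaled = RespirationTrace(samples=trace.samples * 7.3, rate=trace.rate)
        _, p2, _ = preprocess(scaled)
        assert len(p1) == len(p2)
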