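"""Smoothing, extremum detection, cycle segmentation and respiratory rate."""

import numpy as np
import pytest

from rhbreath import (
    SampledSignal,
    detect_deep_breaths,
    find_breath_extrema,
    resample,
    respiratory_rate,
    segment_breath_cycles,
    smooth_signal,
)
from rhbreath.segment import BreathCycle, Segmentation


def _grid_signal(recording, grid_hz=100.0, cutoff=2.0):
    return smooth_signal(resample(recording.rh, grid_hz), cutoff)


class TestSmoothing:
    def test_constant_unchanged(self):
        sig = SampledSignal(np.full(1000, 42.0), 100.0)
        np.testing.assert_allclose(smooth_signal(sig, 2.0).values, 42.0, rtol=1e-9)

    def test_high_frequency_tone_suppressed(self):
        """0.3 Hz breathing + 50 Hz interference, 2 Hz cutoff: the 50 Hz
        residual drops below 1% of its input amplitude."""
        t = np.arange(0, 20, 1 / 200)
        sig = SampledSignal(np.sin(2 * np.pi * 0.3 * t) + 0.5 * np.sin(2 * np.pi * 50 * t), 200.0)
        out = smooth_signal(sig, 2.0)
        spectrum = np.abs(np.fft.rfft(out.values)) / len(t) * 2
        freqs = np.fft.rfftfreq(len(t), 1 / 200)
        assert spectrum[np.argmin(np.abs(freqs - 50.0))] < 0.005
        assert spectrum[np.argmin(np.abs(freqs - 0.3))] > 0.9

    def test_zero_phase_peak_not_shifted(self):
        t = np.arange(0, 10, 1 / 100)
        pulse = np.exp(-((t - 5.0) ** 2) / 0.5)
        sig = SampledSignal(pulse, 100.0)
        out = smooth_signal(sig, 2.0)
        assert abs(int(np.argmax(out.values)) - int(np.argmax(pulse))) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        sig = SampledSignal(np.zeros(100), 10.0)
        with pytest.raises(ValueError, match="cutoff"):
            smooth_signal(sig, 6.0)


class TestExtrema:
    def test_monotone_signal_has_no_interior_extrema(self):
        sig = SampledSignal(np.linspace(0, 10, 200), 10.0)
        minima, maxima = find_breath_extrema(sig, 0.1, 0.1)
        assert len(minima) == 0 and len(maxima) == 0

    def test_sine_extrema_match_closed_form(self):
        """sin(2*pi*0.25*t) over 60 s has 15 maxima; minima counts differ
        only by endpoint effects."""
        t = np.arange(0, 60, 1 / 50)
        sig = SampledSignal(np.sin(2 * np.pi * 0.25 * t), 50.0)
        minima, maxima = find_breath_extrema(sig, 0.5, 1.0)
        assert len(maxima) == 15
        assert len(minima) in (14, 15)

    def test_plateau_resolves_to_first_sample(self):
        x = np.concatenate([np.arange(10.0), np.full(5, 10.0), np.arange(10.0)[::-1]])
        sig = SampledSignal(x, 10.0)
        _, maxima = find_breath_extrema(sig, 1.0, 0.1)
        assert list(maxima) == [10]

    def test_extrema_alternate(self, small_recording):
        sig = _grid_signal(small_recording)
        minima, maxima = find_breath_extrema(sig)
        merged = sorted([(i, "m") for i in minima] + [(i, "M") for i in maxima])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_datasheet_noise_does_not_change_counts(self, noiseless_recording, small_config):
        import dataclasses

        from rhbreath import simulate_subject

        noisy = simulate_subject(
            dataclasses.replace(
                noiseless_recording.config, noise_sd_rh_pct=0.02, seed=1
            )
        )
        n_clean = len(find_breath_extrema(_grid_signal(noiseless_recording))[0])
        n_noisy = len(find_breath_extrema(_grid_signal(noisy))[0])
        assert abs(n_clean - n_noisy) <= 1


class TestSegmentation:
    def test_three_minima_two_maxima_two_cycles(self):
        t = np.arange(0, 4, 0.1)
        sig = SampledSignal(np.interp(t, [0, 1, 2, 3, 4], [0, 5, 0, 6, 0]), 10.0)
        seg = segment_breath_cycles(sig, np.array([0, 20, 39]), np.array([10, 30]))
        assert len(seg) == 2
        assert [c.peak_idx for c in seg.cycles] == [10, 30]

    def test_fewer_than_two_minima_empty(self):
        sig = SampledSignal(np.sin(np.linspace(0, np.pi, 100)), 100.0)
        seg = segment_breath_cycles(sig, np.array([]), np.array([50]))
        assert len(seg) == 0

    def test_cycles_tile_the_span_between_first_and_last_minimum(self, small_recording):
        sig = _grid_signal(small_recording)
        minima, maxima = find_breath_extrema(sig)
        seg = segment_breath_cycles(sig, minima, maxima)
        assert seg.cycles[0].start_idx == minima[0]
        assert seg.cycles[-1].end_idx == minima[-1]
        for a, b in zip(seg.cycles, seg.cycles[1:]):
            assert a.end_idx == b.start_idx

    def test_noiseless_boundaries_match_truth_within_one_sample(self, noiseless_recording):
        sig = _grid_signal(noiseless_recording)
        minima, maxima = find_breath_extrema(sig)
        seg = segment_breath_cycles(sig, minima, maxima)
        truth_t = noiseless_recording.truth.boundary_times_s[1:-1]
        det_t = np.asarray(minima, dtype=float) / sig.sample_rate_hz
        # truth boundaries lie off the analysis grid, so the discrete argmin
        # can land 1 sample past the nearest grid point: bound is 1.5 samples
        for tt in truth_t:
            assert np.abs(det_t - tt).min() <= 1.5 / sig.sample_rate_hz + 1e-9


class TestDeepDetection:
    def test_equal_amplitudes_give_no_deep_events(self):
        t = np.arange(0, 60, 0.01)
        sig = SampledSignal(50 + 10 * np.sin(2 * np.pi * 0.25 * t), 100.0)
        minima, maxima = find_breath_extrema(sig)
        seg = detect_deep_breaths(sig, segment_breath_cycles(sig, minima, maxima))
        assert seg.deep_events == []

    def test_synthetic_deep_events_all_recovered(self, small_recording):
        sig = _grid_signal(small_recording)
        minima, maxima = find_breath_extrema(sig)
        seg = detect_deep_breaths(sig, segment_breath_cycles(sig, minima, maxima))
        assert len(seg.deep_events) == len(small_recording.truth.deep_events)

    def test_second_difference_sign_change_located_at_inflection(self):
        from rhbreath.segment import _second_difference_sign_changes

        t = np.linspace(-1, 1, 201)
        anchors = _second_difference_sign_changes(t**3)  # inflection at t=0
        assert len(anchors) == 1
        assert abs(int(anchors[0]) - 100) <= 1

    def test_event_boundaries_are_troughs_or_curvature_sign_changes(self, small_recording):
        """Each refined event boundary either stays at the bounding trough
        or sits exactly on a second-difference sign change."""
        from rhbreath.segment import _second_difference_sign_changes

        sig = _grid_signal(small_recording)
        minima, maxima = find_breath_extrema(sig)
        seg = detect_deep_breaths(sig, segment_breath_cycles(sig, minima, maxima))
        anchors = set(_second_difference_sign_changes(sig.values).tolist())
        assert seg.deep_events
        for ev in seg.deep_events:
            c_in = seg.cycles[ev.inhale_cycle]
            c_ex = seg.cycles[ev.exhale_cycle]
            assert ev.start_idx == c_in.start_idx or ev.start_idx in anchors
            assert ev.end_idx == c_ex.end_idx or ev.end_idx in anchors


class TestRespiratoryRate:
    def test_direct_count_in_one_window(self):
        sig = SampledSignal(np.zeros(6000), 100.0)  # 60 s
        minima = np.linspace(100, 5900, 18).astype(int)
        out = respiratory_rate(sig, minima, 60.0, refine=False)
        assert out == [(0.0, 18.0)]

    def test_sine_rate_matches_analytic_period(self):
        t = np.arange(0, 120, 0.02)
        sig = SampledSignal(np.sin(2 * np.pi * 0.25 * t), 50.0)
        minima, _ = find_breath_extrema(sig, 0.5, 1.0)
        out = respiratory_rate(sig, minima, 60.0)
        assert [r for _, r in out] == [15.0, 15.0]

    def test_flat_signal_rate_zero(self):
        sig = SampledSignal(np.zeros(12000), 100.0)
        out = respiratory_rate(sig, np.array([], dtype=int), 60.0)
        assert [r for _, r in out] == [0.0, 0.0]

    def test_window_longer_than_recording_flagged(self):
        sig = SampledSignal(np.zeros(500), 100.0)  # 5 s
        with pytest.warns(UserWarning, match="exceeds"):
            out = respiratory_rate(sig, np.array([100, 300]), 60.0, refine=False)
        assert len(out) == 1

    def test_minima_and_maxima_rates_agree(self, small_recording):
        """RR from minima equals RR from maxima to within one breath/min."""
        sig = _grid_signal(small_recording)
        minima, maxima = find_breath_extrema(sig)
        rr_min = np.array([r for _, r in respiratory_rate(sig, minima)])
        rr_max = np.array([r for _, r in respiratory_rate(sig, maxima)])
        assert np.abs(rr_min - rr_max).max() <= 1.0

    def test_constant_rate_recovered_within_half_breath(self, noiseless_recording):
        """With zero rate jitter the windowed mean recovers the configured
        respiratory rate to better than 0.5 breaths/min."""
        import dataclasses

        from rhbreath import simulate_subject

        rec = simulate_subject(
            dataclasses.replace(noiseless_recording.config, rr_sd_bpm=0.0)
        )
        sig = _grid_signal(rec)
        minima, _ = find_breath_extrema(sig)
        rr = np.array([r for _, r in respiratory_rate(sig, minima)])
        assert abs(rr.mean() - rec.config.rr_mean_bpm) < 0.5


class TestDataStructures:
    def test_cycle_ordering_enforced(self):
        with pytest.raises(ValueError, match="start < peak < end"):
            BreathCycle(5, 3, 10, 1.0)

    def test_overlapping_cycles_rejected(self):
        a = BreathCycle(0, 5, 10, 1.0)
        b = BreathCycle(8, 12, 15, 1.0)
        with pytest.raises(ValueError, match="non-overlapping"):
            Segmentation(cycles=[a, b])
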