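"""Smoothing filters, peak-valley extraction and decision-tree checks."""

import math

import numpy as np
import pytest
from scipy.signal import find_peaks as scipy_find_peaks

from qstm.session import TimeLedger
from qstm.strokes import (
    FilterConfig,
    PeakValleyPair,
    StrokeEvent,
    binomial_kernel,
    binomial_lpf,
    build_pairs,
    butterworth_lpf,
    confidence_ratio,
    detect_strokes,
    filter_redundant_peaks,
    find_peaks_valleys,
    segment_bursts,
    stroke_frequency,
)


class TestBinomialFilter:
    def test_kernel_is_normalized_pascal_row(self):
        w = binomial_kernel(5)
        assert np.allclose(w, np.array([1, 4, 6, 4, 1]) / 16.0)

    def test_constant_stream_unchanged(self):
        f = np.full(80, 3.7)
        assert np.allclose(binomial_lpf(f, 25), f)

    def test_impulse_response_is_binomial_and_sums_to_one(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = binomial_lpf(x, 25)
        # direct convolution oracle
        expected = np.convolve(x, binomial_kernel(25), mode="same")
        assert np.allclose(out, expected, atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_output_length_equals_input_length(self):
        assert len(binomial_lpf(np.arange(10.0), 25)) == 10


class TestButterworth:
    def test_dc_gain_unity(self):
        f = np.full(400, 5.0)
        assert np.allclose(butterworth_lpf(f), f, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        y = butterworth_lpf(x)
        mid = slice(500, 1500)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated_40db(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 40.0 * t)
        y = butterworth_lpf(x)
        assert np.max(np.abs(y[500:1500])) < 1e-2

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lpf(np.zeros(100), cutoff_hz=60.0, fs_hz=100.0)


class TestFindPeaksValleys:
    def test_monotone_stream_has_no_interior_peaks(self):
        valleys, peaks = find_peaks_valleys(np.linspace(0, 1, 50))
        assert len(peaks) == 0

    def test_sine_cycles_counted_against_brute_force(self):
        t = np.arange(500) / 100.0
        f = 2.0 + np.sin(2 * np.pi * 1.0 * t)  # 5 full cycles
        valleys, peaks = find_peaks_valleys(f)
        # brute-force oracle: strict interior local maxima
        brute = [
            i
            for i in range(1, len(f) - 1)
            if f[i] > f[i - 1] and f[i] >= f[i + 1]
        ]
        assert len(peaks) == len(brute) == 5
        # independent library cross-check
        scipy_peaks, _ = scipy_find_peaks(f)
        assert np.array_equal(peaks, scipy_peaks)

    def test_alternation_and_boundary_valleys(self):
        f = np.array([1.0, 3.0, 1.0, 4.0, 1.0])
        valleys, peaks = find_peaks_valleys(f)
        assert len(valleys) == len(peaks) + 1
        interleaved = np.empty(len(valleys) + len(peaks), dtype=int)
        interleaved[0::2] = valleys
        interleaved[1::2] = peaks
        assert np.all(np.diff(interleaved) > 0)

    def test_plateau_peak_assigned_to_first_sample(self):
        f = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        _, peaks = find_peaks_valleys(f)
        assert list(peaks) == [2]

    def test_too_short_stream_rejected(self):
        with pytest.raises(ValueError):
            find_peaks_valleys(np.array([1.0, 2.0]))


class TestConfidenceRatio:
    @pytest.mark.parametrize(
        "v, p, v_next, expected",
        [
            (2.0, 10.0, 2.0, 1.0),  # symmetric stroke
            (8.0, 10.0, 2.0, 0.25),  # shallow rise, deep fall
            (2.0, 10.0, 10.0 - 1e-12, math.inf),  # degenerate fall
        ],
    )
    def test_hand_computed_ratios(self, v, p, v_next, expected):
        pair = PeakValleyPair((0, v), (1, p), (2, v_next))
        assert confidence_ratio(pair) == expected


def _triangle_train(k, peak=10.0, base=2.0, half=10):
    """k clean symmetric triangles; returns the series."""
    up = np.linspace(base, peak, half, endpoint=False)
    down = np.linspace(peak, base, half, endpoint=False)
    return np.concatenate([np.concatenate([up, down]) for _ in range(k)] + [[base]])


class TestRedundantPeakFilter:
    def test_symmetric_train_fully_retained(self):
        f = _triangle_train(6)
        valleys, peaks = find_peaks_valleys(f)
        v2, p2 = filter_redundant_peaks(f, valleys, peaks, (0.33, 3.0))
        assert len(p2) == 6

    def test_shoulder_ripple_merged_into_primary(self):
        # primary peak 10 with a small shoulder (dip 9.5, bump 9.8) on the
        # fall: the shoulder's ratio (rise 0.3 / fall ~7.8) rejects it, and
        # the primary's degenerate fall to the dip rejects in the other
        # direction; one stroke must remain with the primary peak retained
        f = np.array([2.0, 4, 6, 8, 10, 9.7, 9.5, 9.8, 8, 6, 4, 2.0])
        valleys, peaks = find_peaks_valleys(f)
        assert len(peaks) == 2
        v2, p2 = filter_redundant_peaks(f, valleys, peaks, (0.33, 3.0))
        assert len(p2) == 1
        assert f[p2[0]] == 10.0

    def test_brute_force_merge_oracle_on_toy_series(self):
        # enumeration oracle: with one redundant shoulder the only valid
        # outcome keeping ratios in band is the single primary cycle
        f = np.array([1.0, 5, 9, 8.6, 8.9, 5, 1.0])
        valleys, peaks = find_peaks_valleys(f)
        v2, p2 = filter_redundant_peaks(f, valleys, peaks, (0.33, 3.0))
        pairs = build_pairs(f, v2, p2)
        assert len(pairs) == 1
        assert 0.33 <= confidence_ratio(pairs[0]) <= 3.0
        assert f[p2[0]] == 9.0

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        f = binomial_lpf(
            2.5 + np.abs(np.sin(np.arange(600) * 0.06)) * 20 + rng.normal(0, 0.4, 600),
            25,
        )
        valleys, peaks = find_peaks_valleys(f)
        v1, p1 = filter_redundant_peaks(f, valleys, peaks, (0.33, 3.0), 1.0)
        v2, p2 = filter_redundant_peaks(f, v1, p1, (0.33, 3.0), 1.0)
        assert np.array_equal(v1, v2)
        assert np.array_equal(p1, p2)

    def test_low_prominence_noise_peaks_dropped(self):
        f = np.array([0.0, 0.3, 0.1, 0.4, 0.05, 0.35, 0.0])
        valleys, peaks = find_peaks_valleys(f)
        _, p2 = filter_redundant_peaks(f, valleys, peaks, (0.33, 3.0), 1.0)
        assert len(p2) == 0


class TestStrokeDetection:
    def test_detected_strokes_ordered_and_non_overlapping(self, two_subsession_run):
        _, _, _, result = two_subsession_run
        strokes = result.strokes
        assert len(strokes) >= 2
        for a, b in zip(strokes[:-1], strokes[1:]):
            assert a.peak_time < b.peak_time
            assert a.end_index <= b.start_index

    def test_half_sine_train_counted_exactly(self):
        fs = 100.0
        t = np.arange(int(20 * fs)) / fs
        f = 2.5 + 20 * np.abs(np.sin(np.pi * 1.5 * t))  # 1.5 Hz strokes
        strokes = detect_strokes(f, fs, FilterConfig(), raw=f)
        assert len(strokes) == 30


class TestStrokeFrequency:
    def test_count_over_treatment_time(self):
        ledger = TimeLedger(contact_time=15.0, dead_time=5.0)
        rate = stroke_frequency(30, ledger)
        assert rate.treatment_rate == pytest.approx(1.5)
        assert rate.contact_rate == pytest.approx(2.0)

    def test_zero_strokes_zero_rate(self):
        rate = stroke_frequency(0, TimeLedger(contact_time=10.0))
        assert rate.treatment_rate == 0.0

    def test_zero_elapsed_rejected(self):
        with pytest.raises(ValueError):
            stroke_frequency(5, TimeLedger())


def _stroke_at(t):
    return StrokeEvent(
        peak_index=int(t * 100),
        peak_force=20.0,
        start_index=int(t * 100) - 20,
        end_index=int(t * 100) + 20,
        duration=0.4,
        peak_time=t,
    )


class TestBurstSegmentation:
    def test_uniform_train_is_one_burst(self):
        strokes = [_stroke_at(1.0 + k) for k in range(10)]
        bursts = segment_bursts(strokes)
        assert len(bursts) == 1
        assert bursts[0].mean_frequency == pytest.approx(1.0)

    def test_pace_change_with_gap_splits(self):
        slow = [_stroke_at(1.0 + k) for k in range(5)]  # 1 Hz
        fast = [_stroke_at(7.0 + k / 3.0) for k in range(5)]  # 3 Hz after 2 s gap
        bursts = segment_bursts(slow + fast)
        assert len(bursts) == 2
        assert bursts[1].mean_frequency == pytest.approx(3.0, rel=0.01)

    def test_subsession_boundary_always_splits(self):
        strokes = [_stroke_at(1.0 + k) for k in range(6)]
        ids = [0, 0, 0, 1, 1, 1]
        bursts = segment_bursts(strokes, subsession_ids=ids)
        assert len(bursts) == 2
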