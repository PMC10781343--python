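import numpy as np
import pytest

from romval import (
    AlignedPair,
    coarse_align_first_peak,
    detect_peaks,
    fine_tune_alignment,
    frames_to_seconds,
    match_samples,
    segment_repetitions,
)
from romval.rom_amplitude import AmplitudeSeries
from romval.temporal_alignment import PeakSet
from romval.errors import AlignmentError, DataError, SegmentationError, ValidationError

from conftest import raised_cosine_series


def series(times, values, **kw):
    return AmplitudeSeries(times=np.asarray(times, float), values=np.asarray(values, float), **kw)


class TestFramesToSeconds:
    def test_mocap_rate(self):
        assert frames_to_seconds(100, 100.0) == 1.0

    def test_camera_rate(self):
        assert frames_to_seconds(30, 30.0) == 1.0

    def test_zero(self):
        assert frames_to_seconds(0, 17.3) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            frames_to_seconds(-1, 30.0)

    def test_bad_fps(self):
        with pytest.raises(ValidationError):
            frames_to_seconds(1, 0.0)


class TestDetectPeaks:
    def test_single_triangular_pulse(self):
        v = np.concatenate([np.linspace(0, 90, 10), np.linspace(90, 0, 10)[1:]])
        s = series(np.arange(len(v)) / 10.0, v)
        peaks = detect_peaks(s)
        assert len(peaks) == 1
        assert peaks.amplitudes[0] == 90.0
        assert peaks.indices[0] == 9

    def test_seven_repetitions_at_known_times(self):
        starts = np.arange(7) * 3.0
        t, v = raised_cosine_series(starts, [90] * 7, 3.0, 30.0, 22.0)
        peaks = detect_peaks(series(t, v))
        assert len(peaks) == 7
        np.testing.assert_allclose(peaks.times, starts + 1.5, atol=1 / 30.0)

    def test_constant_series_no_peaks(self):
        s = series(np.arange(10) / 10.0, np.full(10, 42.0))
        assert len(detect_peaks(s)) == 0

    def test_all_missing_rejected(self):
        s = series(np.arange(5) / 10.0, np.full(5, np.nan))
        with pytest.raises(DataError):
            detect_peaks(s)

    def test_missing_breaks_neighborhood(self):
        # two pulses, the valley between them removed -> still two peaks
        t, v = raised_cosine_series([0.0, 4.0], [90, 80], 3.0, 30.0, 8.0)
        v[(t > 3.0) & (t < 4.0)] = np.nan
        peaks = detect_peaks(series(t, v))
        assert len(peaks) == 2

    def test_min_separation_enforced(self):
        t, v = raised_cosine_series([0.0, 3.0], [90, 80], 3.0, 30.0, 7.0)
        peaks = detect_peaks(series(t, v), min_separation_s=5.0)
        assert len(peaks) == 1
        assert peaks.amplitudes[0] == pytest.approx(90.0, abs=1.0)


class TestCoarseAlign:
    def test_subtraction(self):
        gt = PeakSet([3.2], [90.0], [0])
        pred = PeakSet([1.2], [88.0], [0])
        assert coarse_align_first_peak(gt, pred) == pytest.approx(2.0)

    def test_identical(self):
        p = PeakSet([1.0, 2.0], [90.0, 91.0], [10, 20])
        assert coarse_align_first_peak(p, p) == 0.0

    def test_empty_rejected(self):
        empty = PeakSet(np.empty(0), np.empty(0), np.empty(0, int))
        with pytest.raises(AlignmentError):
            coarse_align_first_peak(empty, empty)


class TestMatchSamples:
    def test_full_match_at_paper_rates(self):
        t, v = raised_cosine_series([0.0], [90.0], 3.0, 100.0, 4.0)
        gt = series(t, v)
        tp, vp = raised_cosine_series([0.0], [90.0], 3.0, 30.0, 4.0)
        pred = series(tp, vp)
        pair = match_samples(gt, pred, offset_s=0.0, tolerance_s=0.005)
        assert len(pair) == len(pred)  # 10 ms grid => nearest gt within 5 ms

    def test_equal_rate_identity_pairing(self):
        t, v = raised_cosine_series([0.0], [90.0], 3.0, 30.0, 4.0)
        gt = series(t, v)
        pair = match_samples(gt, gt, offset_s=0.0, tolerance_s=0.001)
        np.testing.assert_array_equal(pair.gt_values, pair.pred_values)
        assert len(pair) == len(gt)

    def test_offset_beyond_duration_rejected(self):
        t, v = raised_cosine_series([0.0], [90.0], 3.0, 30.0, 4.0)
        with pytest.raises(AlignmentError):
            match_samples(series(t, v), series(t, v), offset_s=100.0, tolerance_s=0.005)

    def test_tolerance_respected(self):
        # a 33 ms offset puts every target 33 ms past the 100 ms gt grid
        t = np.arange(0.0, 1.0, 0.1)
        gt = series(t, np.linspace(0, 90, len(t)))
        pred = series(t, np.linspace(0, 90, len(t)))
        with pytest.raises(AlignmentError):
            match_samples(gt, pred, offset_s=0.033, tolerance_s=0.005)
        pair = match_samples(gt, pred, offset_s=0.033, tolerance_s=0.04)
        assert len(pair) > 0

    def test_missing_values_dropped(self):
        t = np.arange(0.0, 1.0, 0.1)
        v = np.linspace(10, 90, len(t))
        v2 = v.copy()
        v2[3] = np.nan
        pair = match_samples(series(t, v), series(t, v2), offset_s=0.0, tolerance_s=0.001)
        assert len(pair) == len(t) - 1


class TestFineTune:
    def _streams(self, amps, offset, gt_fps=100.0, pred_fps=30.0, period=3.0):
        starts = np.arange(len(amps)) * period
        total = starts[-1] + period + 1.0
        t, v = raised_cosine_series(starts, amps, period, gt_fps, total)
        gt = series(t, v)
        tp = np.arange(0.0, total - offset, 1.0 / pred_fps)
        vp = np.zeros_like(tp)
        for s, a in zip(starts, amps):
            m = (tp + offset >= s) & (tp + offset <= s + period)
            vp[m] = a * 0.5 * (1 - np.cos(2 * np.pi * (tp[m] + offset - s) / period))
        return gt, series(tp, vp)

    def test_recovers_generator_offset(self):
        amps = [85, 95, 75, 90, 80]
        gt, pred = self._streams(amps, offset=1.7)
        pair = fine_tune_alignment(gt, pred, detect_peaks(gt), detect_peaks(pred))
        assert abs(pair.offset_s - 1.7) <= 1 / 30.0
        r = np.corrcoef(pair.gt_values, pair.pred_values)[0, 1]
        assert r >= 0.999

    def test_subsampled_identity(self):
        amps = [85, 95, 75]
        gt, _ = self._streams(amps, offset=0.0)
        sub = series(gt.times[::10], gt.values[::10])  # same clock, 10 fps
        pair = fine_tune_alignment(gt, sub, detect_peaks(gt), detect_peaks(sub))
        assert pair.offset_s == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(pair.gt_values, pair.pred_values, atol=1e-12)

    def test_skips_spurious_first_peak(self):
        amps = [80, 95, 70, 90]
        starts = 3.0 + np.arange(len(amps)) * 3.0
        total = starts[-1] + 4.0
        tg, vg = raised_cosine_series(starts, amps, 3.0, 100.0, total)
        # spurious low early pulse in gt only (familiarization wiggle)
        _, v_extra = raised_cosine_series([0.3], [40.0], 1.5, 100.0, total)
        gt2 = series(tg, np.maximum(vg, v_extra))
        tp, vp = raised_cosine_series(starts, amps, 3.0, 30.0, total)
        pred = series(tp, vp)
        gt_peaks = detect_peaks(gt2)
        pred_peaks = detect_peaks(pred)
        assert len(gt_peaks) == len(amps) + 1  # the spurious peak is detected
        coarse = coarse_align_first_peak(gt_peaks, pred_peaks)
        pair = fine_tune_alignment(gt2, pred, gt_peaks, pred_peaks)
        assert abs(pair.offset_s - 0.0) <= 1 / 30.0
        assert abs(coarse - 0.0) > 0.5  # coarse was fooled
        coarse_pair = match_samples(gt2, pred, coarse, 0.005)
        r_fine = np.corrcoef(pair.gt_values, pair.pred_values)[0, 1]
        r_coarse = np.corrcoef(coarse_pair.gt_values, coarse_pair.pred_values)[0, 1]
        assert r_fine >= r_coarse

    def test_fine_never_below_coarse(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            amps = rng.uniform(60, 100, size=4)
            off = rng.uniform(0, 2)
            gt, pred = self._streams(amps, offset=off)
            noisy = series(pred.times, np.clip(pred.values + rng.normal(0, 2, len(pred)), 0, 180))
            gt_peaks, pred_peaks = detect_peaks(gt), detect_peaks(noisy)
            coarse = coarse_align_first_peak(gt_peaks, pred_peaks)
            pair = fine_tune_alignment(gt, noisy, gt_peaks, pred_peaks)
            coarse_pair = match_samples(gt, noisy, coarse, 0.005)
            r_fine = np.corrcoef(pair.gt_values, pair.pred_values)[0, 1]
            r_coarse = np.corrcoef(coarse_pair.gt_values, coarse_pair.pred_values)[0, 1]
            assert r_fine >= r_coarse - 1e-12


def _aligned_from(t, v):
    return AlignedPair(times=t, gt_values=v, pred_values=v, offset_s=0.0, match_tolerance_s=0.005)


class TestSegmentRepetitions:
    def _protocol_series(self, amps=None, fps=30.0):
        amps = amps if amps is not None else [90.0] * 14
        starts = [i * 3.0 for i in range(7)] + [31.0 + i * 3.0 for i in range(7)]
        total = starts[-1] + 3.0 + 1.0
        return raised_cosine_series(starts, amps, 3.0, fps, total)

    def test_protocol_yields_14_windows(self):
        t, v = self._protocol_series()
        aligned = _aligned_from(t, v)
        windows = segment_repetitions(aligned, detect_peaks(series(t, v)))
        assert len(windows) == 14
        for w in windows:
            assert w.start_s < w.peak_time_s < w.end_s
        for a, b in zip(windows, windows[1:]):
            assert a.end_s <= b.start_s

    def test_half_amplitude_rep_excluded(self):
        amps = [90.0] * 14
        amps[4] = 45.0
        t, v = self._protocol_series(amps)
        aligned = _aligned_from(t, v)
        windows = segment_repetitions(aligned, detect_peaks(series(t, v)), min_peak_frac=0.6)
        assert len(windows) == 13
        # the excluded pulse (starting at 12 s) lies inside no window
        for w in windows:
            assert not (w.start_s < 13.5 < w.end_s)

    def test_single_pulse(self):
        t, v = raised_cosine_series([1.0], [90.0], 3.0, 30.0, 6.0)
        aligned = _aligned_from(t, v)
        windows = segment_repetitions(aligned, detect_peaks(series(t, v)))
        assert len(windows) == 1
        assert windows[0].start_s <= 1.1 and windows[0].end_s >= 3.9

    def test_no_peaks_rejected(self):
        t = np.arange(0.0, 1.0, 0.1)
        aligned = _aligned_from(t, np.zeros_like(t))
        with pytest.raises(SegmentationError):
            segment_repetitions(aligned, PeakSet(np.empty(0), np.empty(0), np.empty(0, int)))
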