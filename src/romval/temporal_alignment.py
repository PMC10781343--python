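"""Temporal alignment of multi-rate amplitude streams and repetition segmentation.

The five-step procedure: (1) frame indices -> seconds; (2) peak detection on
both streams; (3) coarse alignment by the first peak pair; (4) nearest-sample
downsampling of the high-rate (ground-truth) stream onto the low-rate
(predicted) clock within a match tolerance; (5) fine-tuning by re-scoring
candidate peak pairings (plus a local offset grid refinement) with the
Pearson correlation of the matched samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import AlignmentError, DataError, SegmentationError, ValidationError
from .rom_amplitude import AmplitudeSeries


@dataclass
class PeakSet:
    times: np.ndarray
    amplitudes: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        if not (len(self.times) == len(self.amplitudes) == len(self.indices)):
            raise ValidationError("PeakSet fields must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AlignedPair:
    """Matched ground-truth/predicted samples on the predicted stream's clock."""

    times: np.ndarray
    gt_values: np.ndarray
    pred_values: np.ndarray
    offset_s: float
    match_tolerance_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gt_values = np.asarray(self.gt_values, dtype=float)
        self.pred_values = np.asarray(self.pred_values, dtype=float)
        if not (len(self.times) == len(self.gt_values) == len(self.pred_values)):
            raise ValidationError("AlignedPair fields must have equal length")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RepetitionWindow:
    start_s: float
    end_s: float
    peak_time_s: float
    peak_amplitude_deg: float

    def __post_init__(self) -> None:
        if not (self.start_s < self.peak_time_s < self.end_s):
            raise ValidationError("repetition window must satisfy start < peak < end")


def frames_to_seconds(frame_index, fps: float):
    """Convert frame index/indices to seconds: frame_index / fps."""
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    idx = np.asarray(frame_index, dtype=float)
    if np.any(idx < 0):
        raise ValidationError("frame index must be non-negative")
    out = idx / fps
    return float(out) if np.isscalar(frame_index) or out.ndim == 0 else out


def detect_peaks(
    series: AmplitudeSeries,
    min_prominence_frac: float = 0.2,
    min_separation_s: float = 1.0,
) -> PeakSet:
    """Local maxima with prominence >= min_prominence_frac * (max - min).

    Missing samples break peak neighborhoods (each contiguous run of valid
    samples is searched separately); the minimum separation is enforced
    globally, keeping higher peaks first.  A series with zero range yields
    no peaks.
    """
    values = series.values
    finite = np.isfinite(values)
    if not finite.any():
        raise DataError("cannot detect peaks on an all-missing series")
    if finite.sum() < 3:
        raise DataError("need at least 3 non-missing samples for peak detection")
    rng = float(np.nanmax(values) - np.nanmin(values))
    if rng <= 0:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    prominence = min_prominence_frac * rng

    candidates: list[int] = []
    # contiguous runs of non-missing samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], finite.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < 3:
            continue
        idx, _ = find_peaks(values[start:stop], prominence=prominence)
        candidates.extend((idx + start).tolist())
    # global min-separation: greedy, highest amplitude first
    candidates.sort(key=lambda i: (-values[i], i))
    kept: list[int] = []
    for i in candidates:
        if all(abs(series.times[i] - series.times[j]) >= min_separation_s for j in kept):
            kept.append(i)
    kept.sort()
    kept_arr = np.asarray(kept, dtype=int)
    return PeakSet(times=series.times[kept_arr], amplitudes=values[kept_arr], indices=kept_arr)


def coarse_align_first_peak(gt_peaks: PeakSet, pred_peaks: PeakSet) -> float:
    """Offset (s) to add to predicted times so the first peaks coincide."""
    if len(gt_peaks) == 0 or len(pred_peaks) == 0:
        raise AlignmentError("cannot align: empty peak set")
    return float(gt_peaks.times[0] - pred_peaks.times[0])


def match_samples(
    gt: AmplitudeSeries,
    pred: AmplitudeSeries,
    offset_s: float,
    tolerance_s: float = 0.005,
) -> AlignedPair:
    """Nearest-sample downsampling of gt onto the predicted clock.

    For each predicted sample at time t the ground-truth sample nearest to
    t + offset_s is selected; the pair is kept iff the time difference is
    within tolerance_s and both values are non-missing.
    """
    if len(gt) == 0 or len(pred) == 0:
        raise AlignmentError("cannot match samples of an empty series")
    gt_t = gt.times
    target = pred.times + offset_s
    pos = np.searchsorted(gt_t, target)
    pos = np.clip(pos, 1, len(gt_t) - 1) if len(gt_t) > 1 else np.zeros_like(pos)
    left = np.clip(pos - 1, 0, len(gt_t) - 1)
    nearest = np.where(np.abs(gt_t[pos] - target) < np.abs(gt_t[left] - target), pos, left)
    dt = np.abs(gt_t[nearest] - target)
    keep = (
        (dt <= tolerance_s + 1e-12)
        & np.isfinite(pred.values)
        & np.isfinite(gt.values[nearest])
    )
    if not keep.any():
        raise AlignmentError(
            f"no matched sample pairs for offset {offset_s:.4f} s at tolerance {tolerance_s} s"
        )
    return AlignedPair(
        times=pred.times[keep],
        gt_values=gt.values[nearest[keep]],
        pred_values=pred.values[keep],
        offset_s=float(offset_s),
        match_tolerance_s=float(tolerance_s),
    )


def _pearson_score(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return -np.inf
    sa, sb = a.std(), b.std()
    if sa <= 0 or sb <= 0:
        return -2.0  # undefined correlation scores below any real r
    return float(np.corrcoef(a, b)[0, 1])


def fine_tune_alignment(
    gt: AmplitudeSeries,
    pred: AmplitudeSeries,
    gt_peaks: PeakSet,
    pred_peaks: PeakSet,
    tolerance_s: float = 0.005,
    n_candidate_peaks: int = 3,
    refine_halfwidth_s: float = 0.3,
    refine_step_s: float = 0.005,
) -> AlignedPair:
    """Select the peak pairing (and local offset refinement) maximizing Pearson r.

    Candidate offsets are gt_peaks.times[i] - pred_peaks.times[j] over the
    first ``n_candidate_peaks`` of each stream (always including the coarse
    first-peak pairing); each is scored by the Pearson correlation of its
    matched samples.  A local grid around the best candidate refines the
    offset below the peak-quantization error.  Ties prefer the offset
    closest to the coarse one.  The result's r never falls below the
    coarse alignment's r because the coarse offset is among the candidates.
    """
    if len(gt_peaks) == 0 or len(pred_peaks) == 0:
        raise AlignmentError("cannot fine-tune: empty peak set")
    coarse = coarse_align_first_peak(gt_peaks, pred_peaks)

    candidates = []
    for ti in gt_peaks.times[:n_candidate_peaks]:
        for tj in pred_peaks.times[:n_candidate_peaks]:
            candidates.append(float(ti - tj))

    def score(offset: float):
        try:
            pair = match_samples(gt, pred, offset, tolerance_s)
        except AlignmentError:
            return -np.inf, None
        if len(pair) < 2:
            return -np.inf, None
        return _pearson_score(pair.gt_values, pair.pred_values), pair

    best = None  # (r, -|offset-coarse|, offset, pair)
    for off in candidates:
        r, pair = score(off)
        if pair is None:
            continue
        key = (r, -abs(off - coarse))
        if best is None or key > best[0]:
            best = (key, off, pair)
    if best is None:
        raise AlignmentError("no candidate peak pairing yields >= 2 matched pairs")

    base = best[1]
    steps = int(round(refine_halfwidth_s / refine_step_s))
    for k in range(-steps, steps + 1):
        off = base + k * refine_step_s
        r, pair = score(off)
        if pair is None:
            continue
        key = (r, -abs(off - coarse))
        if key > best[0]:
            best = (key, off, pair)
    return best[2]


def segment_repetitions(
    aligned: AlignedPair,
    peaks: PeakSet,
    min_peak_frac: float = 0.5,
) -> list[RepetitionWindow]:
    """One window per retained peak, bounded by the nearest flanking minima.

    Peaks below ``min_peak_frac`` times the median peak amplitude (resting
    wiggles, familiarization, uncompleted trials) are discarded.  Between
    two retained peaks the right boundary of the earlier window is the
    first minimum occurrence and the left boundary of the later window the
    last occurrence, so windows never overlap.  ``peaks`` must have been
    detected on the aligned ground-truth values.
    """
    if len(peaks) == 0:
        raise SegmentationError("no peaks to segment")
    retained = peaks.indices[peaks.amplitudes >= min_peak_frac * float(np.median(peaks.amplitudes))]
    if retained.size == 0:
        raise SegmentationError("no peaks retained after amplitude filtering")

    vals = np.where(np.isfinite(aligned.gt_values), aligned.gt_values, np.inf)
    n = len(vals)
    windows = []
    for k, p in enumerate(retained):
        lo = int(retained[k - 1]) if k > 0 else 0
        hi = int(retained[k + 1]) if k + 1 < len(retained) else n - 1
        left_seg = vals[lo:p]
        right_seg = vals[p + 1 : hi + 1]
        if left_seg.size == 0 or right_seg.size == 0:
            continue  # peak at the series boundary: no flanking minimum
        # last occurrence of the left minimum, first occurrence of the right
        left = lo + left_seg.size - 1 - int(np.argmin(left_seg[::-1]))
        right = p + 1 + int(np.argmin(right_seg))
        windows.append(
            RepetitionWindow(
                start_s=float(aligned.times[left]),
                end_s=float(aligned.times[right]),
                peak_time_s=float(aligned.times[p]),
                peak_amplitude_deg=float(aligned.gt_values[p]),
            )
        )
    if not windows:
        raise SegmentationError("no valid repetition windows")
    return windows
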