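"""Burst segmentation and fixed-length feature extraction.

A contraction event is detected from the moving-RMS envelope of the
(filtered) recording: samples whose 100 ms envelope exceeds k times the
rest level (k = 3) form candidate bursts; near-in-time bursts are merged,
sub-300 ms blips are dropped, and long all-rest stretches emit one
rest/involuntary segment so the classifier also sees the NIM class at
inference time.

Each segment is summarized by four features — duration, RMS, mean absolute
value and zero-crossing rate.  Duration is the quantity that defines the
contraction classes; RMS/MAV/ZCR are the standard sEMG time-domain
features that separate voluntary bursts from involuntary activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .recording import EmgRecording
from .synthetic import ContractionClass, LabelInterval

FEATURE_NAMES = ("duration_s", "rms_mv", "mav_mv", "zcr_hz")

ENVELOPE_WINDOW_S = 0.1
THRESHOLD_K = 3.0
MERGE_GAP_S = 0.5
MIN_BURST_S = 0.3
MIN_REST_SEGMENT_S = 2.0


@dataclass
class Segment:
    """A detected (or ground-truth) stretch of one contraction event.

    ``kind`` records how the segment was found: ``"burst"`` for
    supra-threshold envelope activity, ``"rest"`` for a long quiet
    stretch.  Only burst segments carry command intent downstream.
    """

    recording: EmgRecording
    start_s: float
    end_s: float
    label: ContractionClass | None = None
    kind: str = "burst"

    @property
    def samples(self) -> np.ndarray:
        return self.recording.samples

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def features(self) -> np.ndarray:
        return extract_features(self)

    @property
    def one_hot(self) -> np.ndarray:
        if self.label is None:
            raise ValueError("segment is unlabeled")
        return one_hot(self.label.value, len(ContractionClass))


def moving_rms(rec: EmgRecording, window_s: float = ENVELOPE_WINDOW_S) -> np.ndarray:
    """Envelope: square root of the centered moving mean of x^2."""
    n_win = int(round(window_s * rec.sample_rate_hz))
    if n_win < 1 or n_win > len(rec):
        raise ValueError(
            f"envelope window ({window_s} s) does not fit the recording "
            f"({rec.duration_s:.3f} s)"
        )
    return np.sqrt(uniform_filter1d(rec.samples**2, size=n_win, mode="nearest"))


def segment_bursts(
    rec: EmgRecording,
    threshold_k: float = THRESHOLD_K,
    window_s: float = ENVELOPE_WINDOW_S,
) -> list[Segment]:
    """Detect contraction events by envelope thresholding.

    The rest level is estimated as the median envelope (rest dominates the
    protocol timeline).  Returns voluntary-candidate segments in time
    order, interleaved with one rest segment per >= 2 s quiet stretch;
    labels are left as None — classification assigns them.
    """
    env = moving_rms(rec, window_s)
    rest_rms = float(np.median(env))
    active = env > threshold_k * rest_rms

    fs = rec.sample_rate_hz
    runs = _runs(active)
    # merge bursts separated by short gaps
    merged: list[list[int]] = []
    max_gap = int(round(MERGE_GAP_S * fs))
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < max_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    min_len = int(round(MIN_BURST_S * fs))
    bursts = [(i0, i1) for i0, i1 in merged if i1 - i0 >= min_len]

    segments = [
        Segment(rec.slice_seconds(*_to_seconds(rec, i0, i1)), *_to_seconds(rec, i0, i1))
        for i0, i1 in bursts
    ]
    # quiet stretches >= 2 s become rest/involuntary segments
    min_rest = int(round(MIN_REST_SEGMENT_S * fs))
    edges = [0] + [i for b in bursts for i in b] + [len(rec)]
    for j0, j1 in zip(edges[::2], edges[1::2]):
        if j1 - j0 >= min_rest:
            t0, t1 = _to_seconds(rec, j0, j1)
            segments.append(Segment(rec.slice_seconds(t0, t1), t0, t1, kind="rest"))
    segments.sort(key=lambda s: s.start_s)
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True in a boolean mask."""
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _to_seconds(rec: EmgRecording, i0: int, i1: int) -> tuple[float, float]:
    return (rec.start_time_s + i0 / rec.sample_rate_hz,
            rec.start_time_s + i1 / rec.sample_rate_hz)


def extract_features(seg: Segment) -> np.ndarray:
    """[duration_s, RMS (mV), MAV (mV), zero-crossing rate (1/s)]."""
    x = seg.samples
    if x.size == 0:
        raise ValueError("cannot extract features from an empty segment")
    duration = seg.duration_s
    rms = float(np.sqrt(np.mean(x**2)))
    mav = float(np.mean(np.abs(x)))
    crossings = int(np.count_nonzero(np.diff(np.signbit(x))))
    zcr = crossings / duration if duration > 0 else 0.0
    return np.array([duration, rms, mav, zcr])


def one_hot(label: int, num_classes: int) -> np.ndarray:
    """Unit basis vector encoding of an integer class label."""
    if not 0 <= label < num_classes:
        raise ValueError(f"label {label} outside [0, {num_classes})")
    v = np.zeros(num_classes)
    v[label] = 1.0
    return v


def label_segments(
    segments: list[Segment], truth: list[LabelInterval], min_overlap: float = 0.5
) -> list[Segment]:
    """Assign ground-truth labels to detected segments by interval overlap.

    A segment takes the class of the truth interval it overlaps most
    (fractionally, relative to the shorter of the two); segments with no
    qualifying overlap are labeled NIM — by construction they are rest or
    involuntary activity.
    """
    labeled = []
    for seg in segments:
        best, best_frac = None, 0.0
        for iv in truth:
            ov = min(seg.end_s, iv.end_s) - max(seg.start_s, iv.start_s)
            denom = min(seg.duration_s, iv.duration_s)
            frac = ov / denom if denom > 0 else 0.0
            if frac > best_frac:
                best, best_frac = iv, frac
        label = best.cls if best is not None and best_frac >= min_overlap else ContractionClass.NIM
        labeled.append(Segment(seg.recording, seg.start_s, seg.end_s, label, seg.kind))
    return labeled
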