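"""Pulse peak/valley detection and beat-interval series construction.

The NN (peak-to-peak) interval series is the substrate for every HRV
feature downstream.  Detection is deliberately simple — adaptive-threshold
local maxima with a refractory spacing — which is adequate for a denoised,
baseline-free pulse waveform; the detector sits behind a single function
so it can be swapped.

Timing is at sample resolution: at the 200 Hz working rate the 5 ms
quantisation is accepted and documented rather than interpolated away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import BeatDetectionError, StructuralError
from .io_core import Segment

logger = logging.getLogger(__name__)


@dataclass
class BeatSeries:
    """Fiducial times (s) and derived interval sequences (ms) for one segment.

    ``nn_ms`` are peak-to-peak intervals, ``vv_ms`` valley-to-valley,
    ``vp_ms`` each valley to the next peak (systolic upstroke time) and
    ``pv_ms`` each peak to the next valley (decay time).
    """

    peak_times: np.ndarray
    valley_times: np.ndarray
    nn_ms: np.ndarray
    vv_ms: np.ndarray
    vp_ms: np.ndarray
    pv_ms: np.ndarray


def detect_peaks(segment: Segment, min_rate_bpm: float = 40.0,
                 max_rate_bpm: float = 180.0) -> np.ndarray:
    """Locate systolic peaks in a preprocessed segment.

    Local maxima must exceed an adaptive threshold — the segment median
    plus half the 75th percentile of positive excursions — and be at least
    one refractory period (60 / max_rate_bpm seconds) apart, which keeps
    dicrotic bumps from being counted as beats.

    Returns peak times in seconds from segment start.  Raises
    :class:`BeatDetectionError` when fewer than 3 peaks survive.
    """
    x = np.asarray(segment.samples, dtype=float)
    base = np.median(x)
    pos = x[x > base] - base
    if pos.size == 0:
        raise BeatDetectionError("segment has no positive excursions")
    height = base + 0.5 * np.percentile(pos, 75)
    distance = max(1, int(round(60.0 / max_rate_bpm * segment.fs)))
    idx, _ = signal.find_peaks(x, height=height, distance=distance)
    if idx.size < 3:
        raise BeatDetectionError(f"only {idx.size} peaks found (need >= 3)")
    times = idx / segment.fs
    nn = np.diff(times) * 1000.0
    max_nn = 60000.0 / min_rate_bpm
    slow = np.flatnonzero(nn > max_nn)
    if slow.size:
        logger.warning("%d NN interval(s) slower than %g bpm in segment",
                       slow.size, min_rate_bpm)
    return times


def detect_valleys(segment: Segment, peak_times: np.ndarray) -> np.ndarray:
    """One valley per inter-peak gap, plus an optional leading valley.

    Each valley is the global minimum strictly between consecutive peaks.
    A leading valley is added when the half-median-NN window before the
    first peak contains samples.
    """
    x = np.asarray(segment.samples, dtype=float)
    peaks_idx = np.round(np.asarray(peak_times) * segment.fs).astype(int)
    if peaks_idx.size < 2:
        raise BeatDetectionError("need >= 2 peaks to place valleys")
    valleys = []
    med_nn_s = float(np.median(np.diff(peak_times)))
    lead_start = max(0, int(round((peak_times[0] - 0.5 * med_nn_s) * segment.fs)))
    if peaks_idx[0] - lead_start > 0:
        seg = x[lead_start:peaks_idx[0]]
        valleys.append(lead_start + int(np.argmin(seg)))
    for a, b in zip(peaks_idx[:-1], peaks_idx[1:]):
        interior = x[a + 1:b]
        if interior.size:
            valleys.append(a + 1 + int(np.argmin(interior)))
    return np.asarray(valleys, dtype=float) / segment.fs


def build_beat_series(peak_times: np.ndarray, valley_times: np.ndarray) -> BeatSeries:
    """Assemble the interval sequences, enforcing peak/valley alternation."""
    peaks = np.asarray(peak_times, dtype=float)
    valleys = np.asarray(valley_times, dtype=float)
    _check_alternation(peaks, valleys)
    nn_ms = np.diff(peaks) * 1000.0
    vv_ms = np.diff(valleys) * 1000.0
    vp, pv = [], []
    for v in valleys:
        nxt = peaks[peaks > v]
        if nxt.size:
            vp.append((nxt[0] - v) * 1000.0)
    for p in peaks:
        nxt = valleys[valleys > p]
        if nxt.size:
            pv.append((nxt[0] - p) * 1000.0)
    return BeatSeries(peaks, valleys, nn_ms, vv_ms,
                      np.asarray(vp), np.asarray(pv))


def _check_alternation(peaks: np.ndarray, valleys: np.ndarray) -> None:
    events = sorted([(t, "p") for t in peaks] + [(t, "v") for t in valleys])
    for (_, a), (_, b) in zip(events[:-1], events[1:]):
        if a == b:
            raise StructuralError("peaks and valleys do not alternate")


def beat_series_from_segment(segment: Segment, min_rate_bpm: float = 40.0,
                             max_rate_bpm: float = 180.0) -> BeatSeries:
    """Convenience: detect peaks and valleys, then build the series."""
    peaks = detect_peaks(segment, min_rate_bpm, max_rate_bpm)
    valleys = detect_valleys(segment, peaks)
    return build_beat_series(peaks, valleys)
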