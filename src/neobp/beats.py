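"""Beat segmentation and per-beat blood-pressure ground truth.

Systolic peaks are detected on the bandpassed waveform (adaptive
prominence threshold, 0.25 s refractory period, i.e. a 240 bpm cap);
beat boundaries are the pre-peak minima. SBP/DBP/MAP are then read from
the *unfiltered* arterial trace over each beat span — the bandpass
removes DC and would destroy the absolute pressure scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["BeatAnnotation", "BPTriplet", "segment_beats", "extract_bp_truth",
           "heart_rate"]

REFRACTORY_S = 0.25  # no two systolic peaks closer than this (HR cap 240 bpm)


class InsufficientBeatsError(ValueError):
    pass


@dataclass(frozen=True)
class BeatAnnotation:
    """Half-open beat span [start, end) with systolic peak and diastolic
    valley sample indices."""

    start: int
    peak: int
    valley: int
    end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.peak < self.end and self.start <= self.valley < self.end):
            raise ValueError("landmarks must lie within [start, end)")


@dataclass(frozen=True)
class BPTriplet:
    """Systolic / diastolic / mean arterial pressure in mmHg."""

    sbp: float
    dbp: float
    map: float

    def __post_init__(self) -> None:
        if not (0 < self.dbp <= self.map <= self.sbp):
            raise ValueError(f"need 0 < dbp <= map <= sbp, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sbp, self.dbp, self.map])


def segment_beats(samples: np.ndarray, fs: float) -> list[BeatAnnotation]:
    """Detect beats on a bandpassed (zero-mean) pulse waveform.

    Flat or beat-free signals yield an empty list, not an error.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("need >= 2 s of signal")
    amp = np.percentile(x, 95) - np.percentile(x, 5)
    if amp <= 0 or not np.isfinite(amp):
        return []
    distance = max(int(REFRACTORY_S * fs), 1)
    peaks, _ = signal.find_peaks(x, prominence=0.3 * amp, distance=distance)
    if len(peaks) < 2:
        return []
    ipi = int(np.median(np.diff(peaks)))
    # boundaries: the diastolic trough preceding each peak, plus one after
    # the final peak when a full inter-beat interval remains
    bounds = []
    lo = max(0, peaks[0] - ipi)
    bounds.append(lo + int(np.argmin(x[lo:peaks[0]])) if peaks[0] > lo else 0)
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        bounds.append(p0 + int(np.argmin(x[p0:p1])))
    if peaks[-1] + ipi <= len(x):
        bounds.append(peaks[-1] + int(np.argmin(x[peaks[-1]:peaks[-1] + ipi])))
        n_full = len(peaks)
    else:
        n_full = len(peaks) - 1
    annotations = []
    for k in range(n_full):
        start, end, peak = bounds[k], bounds[k + 1], peaks[k]
        if end <= start or not (start <= peak < end):
            continue
        valley = start + int(np.argmin(x[start:end]))
        annotations.append(BeatAnnotation(start=start, peak=peak, valley=valley, end=end))
    return annotations


def extract_bp_truth(ial_samples: np.ndarray, beat: BeatAnnotation,
                     fs: float | None = None) -> BPTriplet:
    """SBP = beat maximum, DBP = beat minimum, MAP = time-average of the
    arterial pressure over the beat (trapezoidal area divided by beat
    duration, using the closed sample span so the integral covers the
    full beat).

    ``ial_samples`` must be the unfiltered arterial trace in mmHg.
    """
    span = np.asarray(ial_samples[beat.start:beat.end], dtype=float)
    if len(span) == 0:
        raise ValueError("empty beat span")
    sbp = float(span.max())
    dbp = float(span.min())
    if beat.end < len(ial_samples):
        closed = np.asarray(ial_samples[beat.start:beat.end + 1], dtype=float)
        mean = float(np.trapezoid(closed) / (beat.end - beat.start))
    else:
        mean = float(span.mean())
    mean = min(max(mean, dbp), sbp)  # guard against edge rounding
    return BPTriplet(sbp=sbp, dbp=dbp, map=mean)


def heart_rate(beats: list[BeatAnnotation], fs: float) -> float:
    """Heart rate in bpm from the median inter-peak interval."""
    if len(beats) < 2:
        raise InsufficientBeatsError("need >= 2 beats for heart rate")
    peaks = np.array([b.peak for b in beats])
    ipi = float(np.median(np.diff(peaks)))
    return 60.0 * fs / ipi
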