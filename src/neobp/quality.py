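"""Pulse-waveform quality grading and exclusion rules.

Windows are graded on a 0 (unusable) to 5 (best) scale. The clinical
grade comes from visual assessment of dicrotic (secondary) peak
resolution and signal noise; here a deterministic rule-based grader
combines three bounded sub-scores computed from the beat-synchronous
ensemble of the window:

* noise score — how little of the window's power is left after
  subtracting the ensemble-average beat;
* secondary-peak resolution — prominence of the dicrotic bump on the
  smoothed ensemble beat, gated by the noise score so spurious bumps in
  noise do not earn credit;
* beat regularity — coefficient of variation of inter-beat intervals.

When a synchronized arterial reference window is available the grader
also reports r, the Pearson coefficient between the two windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .beats import BeatAnnotation, BPTriplet, segment_beats
from .preprocess import _resample_beat

__all__ = ["QualityScore", "ExclusionRule", "grade_window",
           "select_best_channel", "apply_exclusions", "NoUsableChannelError"]

#: sub-score weights (noise, secondary-peak, regularity); sum to 1
GRADE_WEIGHTS = (0.5, 0.25, 0.25)


class NoUsableChannelError(ValueError):
    """All four sensor channels are degenerate in this window."""


@dataclass(frozen=True)
class QualityScore:
    q: float  # in [0, 5]
    r: Optional[float] = None  # vs synchronized IAL reference, when present

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 5.0):
            raise ValueError(f"q must lie in [0, 5], got {self.q}")
        if self.r is not None and not (-1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise ValueError(f"r must lie in [-1, 1], got {self.r}")


@dataclass(frozen=True)
class ExclusionRule:
    """Window-level exclusion thresholds.

    The arterial reference must have SNR strictly above ``snr_min`` and
    per-component BP within [0, 200/175/150] mmHg for SBP/MAP/DBP. The q
    threshold mirrors the evaluation gate |Q| > 2.5; the r threshold is
    a configurable knob (no published value exists).
    """

    q_min: float = 2.5
    r_min: float = 0.8
    snr_min: float = 5.0
    sbp_max: float = 200.0
    map_max: float = 175.0
    dbp_max: float = 150.0
    bp_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sbp_max > self.map_max > self.dbp_max > 0):
            raise ValueError("require sbp_max > map_max > dbp_max > 0")


def _ensemble(window: np.ndarray, beats: Sequence[BeatAnnotation]) -> tuple[np.ndarray, float]:
    """Ensemble-average beat (common length) and residual/signal power ratio."""
    L = int(np.median([b.end - b.start for b in beats]))
    mat = np.stack([_resample_beat(window[b.start:b.end], L) for b in beats])
    mat = mat - mat.mean(axis=1, keepdims=True)
    template = mat.mean(axis=0)
    p_sig = float(np.mean(template**2))
    p_res = float(np.mean((mat - template) ** 2))
    nsr = p_res / p_sig if p_sig > 0 else np.inf
    return template, nsr


def _secondary_peak_score(template: np.ndarray) -> float:
    """Detectability of the dicrotic inflection on the descending limb.

    Uses the smoothed negative second derivative after the systolic
    peak: a resolvable notch/bump produces a clear local maximum there.
    """
    L = len(template)
    if L < 12:
        return 0.0
    win = max(3, L // 12)
    smoothed = np.convolve(template, np.ones(win) / win, mode="same")
    peak = int(np.argmax(smoothed))
    tail = smoothed[peak:]
    if len(tail) < 8:
        return 0.0
    d2 = np.diff(tail, 2)
    amp = np.ptp(template)
    if amp <= 0:
        return 0.0
    # bump curvature relative to overall beat amplitude
    curv = float(np.max(d2)) / amp * L**2 / 40.0
    return float(np.clip(curv, 0.0, 1.0))


def grade_window(window: np.ndarray, fs: float,
                 reference_window: Optional[np.ndarray] = None) -> QualityScore:
    """Grade one normalized window on the 0-5 quality scale.

    ``window`` must be min-max normalized (values within [0, 1]); grades
    are therefore invariant to any affine rescaling of the raw sensor
    signal. Requires at least 2 detectable beats; windows with fewer
    grade as 0.
    """
    w = np.asarray(window, dtype=float)
    if w.min() < -1e-9 or w.max() > 1.0 + 1e-9:
        raise ValueError("grade_window expects a min-max normalized window")
    r = None
    if reference_window is not None:
        ref = np.asarray(reference_window, dtype=float)
        if len(ref) == len(w) and np.std(ref) > 0 and np.std(w) > 0:
            r = float(stats.pearsonr(w, ref)[0])
    centered = w - np.mean(w)
    beats = segment_beats(centered, fs)
    if len(beats) < 2:
        return QualityScore(q=0.0, r=r)
    template, nsr = _ensemble(centered, beats)
    noise_score = float(np.exp(-3.0 * nsr))
    peak_score = _secondary_peak_score(template) * noise_score
    ipi = np.diff([b.peak for b in beats]) if len(beats) > 2 else np.array(
        [beats[1].peak - beats[0].peak])
    cv = float(np.std(ipi) / np.mean(ipi)) if np.mean(ipi) > 0 else 1.0
    # regularity is damped when the ensemble residual is large: interval
    # statistics of spurious noise "beats" carry no credit
    regularity = float(np.clip(1.0 - 5.0 * cv, 0.0, 1.0)) * (0.3 + 0.7 * noise_score)
    wn, wp, wr = GRADE_WEIGHTS
    q = 5.0 * (wn * noise_score + wp * peak_score + wr * regularity)
    return QualityScore(q=float(np.clip(q, 0.0, 5.0)), r=r)


def select_best_channel(windows: Sequence[np.ndarray], fs: float,
                        reference_window: Optional[np.ndarray] = None,
                        ) -> tuple[int, QualityScore]:
    """Pick the best of the 4 sensor channels for one window.

    Channels are compared by q; ties break to the lowest index.
    Degenerate (constant) channels are skipped; if all four are
    degenerate the window is unusable.
    """
    if len(windows) != 4:
        raise ValueError("expected exactly 4 candidate channel windows")
    best: tuple[int, QualityScore] | None = None
    for i, w in enumerate(windows):
        w = np.asarray(w, dtype=float)
        if np.ptp(w) <= 0 or not np.all(np.isfinite(w)):
            continue
        lo, hi = w.min(), w.max()
        score = grade_window((w - lo) / (hi - lo), fs, reference_window)
        if best is None or score.q > best[1].q:
            best = (i, score)
    if best is None:
        raise NoUsableChannelError("all four channels degenerate")
    return best


def apply_exclusions(bp_truth: Optional[BPTriplet], snr: Optional[float],
                     score: QualityScore,
                     rule: ExclusionRule = ExclusionRule()) -> tuple[bool, str]:
    """Apply all exclusion gates to one window.

    Returns ``(keep, reason)`` where ``reason`` names the first failing
    rule ("ok" when kept). Gates, in order: quality q, regression r
    (only when a reference exists), arterial SNR (strict: exactly 5.0
    is dropped), and per-component BP range.
    """
    if score.q <= rule.q_min:
        return False, "quality_q"
    if score.r is not None and score.r < rule.r_min:
        return False, "regression_r"
    if snr is not None and snr <= rule.snr_min:
        return False, "snr"
    if bp_truth is not None:
        if not (rule.bp_min < bp_truth.sbp <= rule.sbp_max):
            return False, "range_SBP"
        if not (rule.bp_min < bp_truth.map <= rule.map_max):
            return False, "range_MAP"
        if not (rule.bp_min < bp_truth.dbp <= rule.dbp_max):
            return False, "range_DBP"
    return True, "ok"
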