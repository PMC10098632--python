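"""Two-stream alignment and paired-database construction.

The unscaled sensor stream and the invasive arterial line (IAL) stream
are recorded by different devices and are offset by an unknown lag; the
sensor stream may additionally lose segments (dropouts), so the offset
drifts over a recording. Alignment is two-stage: a *global* lag is the
median of per-window cross-correlation lags over high-quality windows
sampled across the whole recording (windows whose two-stream heart
rates disagree by more than 5 bpm are rejected as mis-locks); a *local*
lag is then refined per window within a bounded drift around the global
value, which absorbs missing data.

Lag convention: sensor sample ``i`` lines up with IAL sample
``i + lag``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .beats import BeatAnnotation, BPTriplet, extract_bp_truth, heart_rate, segment_beats
from .preprocess import (FilterSpec, TooShortError, WindowSpec, bandpass_filter,
                         compute_snr, detect_hfov, normalize_window, notch_filter)
from .quality import (ExclusionRule, NoUsableChannelError, QualityScore,
                      apply_exclusions, grade_window, select_best_channel)
from .simulate import PatientDataset, WaveformRecord

__all__ = ["SyncResult", "PairedWindow", "ExclusionLogEntry", "SyncFailure",
           "estimate_global_lag", "refine_local_lag", "build_paired_database",
           "MAX_WINDOWS_PER_PATIENT", "MIN_WINDOWS_PER_PATIENT"]

MAX_LAG_SAMPLES = 1250      # +-10 s global search at 125 Hz
MAX_DRIFT_SAMPLES = 250     # +-2 s local refinement around the global lag
HR_AGREEMENT_BPM = 5.0
MAX_WINDOWS_PER_PATIENT = 5000
MIN_WINDOWS_PER_PATIENT = 10


class SyncFailure(RuntimeError):
    """Too few usable windows to estimate the global lag."""


@dataclass
class SyncResult:
    global_lag_samples: int
    per_window: list[tuple[str, int, float]]  # (window_id, local lag, correlation)


@dataclass
class PairedWindow:
    """The training/evaluation atom: one synchronized, normalized sensor
    window with its arterial ground truth and patient covariates."""

    window_id: str
    patient_id: str
    sensor_samples: np.ndarray  # min-max normalized, beat-onset aligned
    bp_truth: BPTriplet
    age_days: float
    weight_kg: float
    quality: QualityScore
    channel: int = 0
    local_lag: int = 0


@dataclass(frozen=True)
class ExclusionLogEntry:
    window_id: str
    patient_id: str
    q: float
    r: Optional[float]
    snr: Optional[float]
    decision: str  # "keep" | "drop"
    reason: str


def _norm_xcorr(win: np.ndarray, stream: np.ndarray, lag_lo: int,
                lag_hi: int, start: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of ``win`` (placed at ``start`` on the
    sensor timeline) against ``stream`` over lags [lag_lo, lag_hi]."""
    L = len(win)
    lo = start + lag_lo
    hi = start + lag_hi + L
    lo_c = max(lo, 0)
    hi_c = min(hi, len(stream))
    if hi_c - lo_c < L:
        return np.empty(0, dtype=int), np.empty(0)
    seg = stream[lo_c:hi_c]
    w = win - win.mean()
    sw = np.sqrt(np.sum(w**2))
    if sw == 0:
        return np.empty(0, dtype=int), np.empty(0)
    dot = np.correlate(seg, w, mode="valid")
    # sliding mean/std of seg over length-L windows
    c1 = np.concatenate(([0.0], np.cumsum(seg)))
    c2 = np.concatenate(([0.0], np.cumsum(seg**2)))
    s1 = c1[L:] - c1[:-L]
    s2 = c2[L:] - c2[:-L]
    var = np.maximum(s2 - s1**2 / L, 0.0)
    denom = sw * np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, dot / denom, -np.inf)
    lags = np.arange(lo_c - start, hi_c - start - L + 1)
    return lags, corr


def estimate_global_lag(sensor: WaveformRecord, ial: WaveformRecord,
                        n_windows: int = 20, seed: int = 0,
                        sync_window_s: float = 30.0,
                        max_lag: int = MAX_LAG_SAMPLES,
                        q_min: float = 0.1,
                        c_min: float = 0.2) -> int:
    """Global inter-stream lag from randomly sampled high-quality windows.

    For each sampled sensor window the lag maximizing normalized
    cross-correlation against the IAL stream is found over ``+-max_lag``;
    windows failing the quality gate, or whose instantaneous heart rates
    disagree across streams by more than 5 bpm, are rejected. The global
    lag is the median of the surviving per-window lags (median, not
    mean, for robustness to occasional mis-locks).

    The quality gate here is deliberately lighter than the pairing gate
    (default ``q_min`` 0.1, rejecting only unusable segments, plus a
    correlation-peak floor ``c_min``): a
    window partly hit by a motion burst grades poorly yet still votes
    the correct lag, and the heart-rate agreement check plus the median
    absorb the occasional mis-lock.

    Correlation windows are deliberately long (default 30 s, much longer
    than the 4 s analysis windows): the pulse is near-periodic, so short
    windows correlate almost as well at offsets of one whole beat; over
    30 s the slow heart-rate wander accumulates enough phase drift to
    break that ambiguity and leave a unique correlation peak.
    """
    fs = sensor.fs_hz
    L = int(round(sync_window_s * fs))
    rng = np.random.default_rng(seed)
    # dense overlapping grid: short recordings still offer enough
    # candidate windows when some are ruined by motion or lag padding
    window = WindowSpec(length_s=sync_window_s, hop_s=sync_window_s / 4.0)
    starts = window.starts(len(sensor.samples), fs)
    # the correlation search clips its IAL segment at the record edges, so
    # edge windows are usable too (their searchable lag range just shrinks)
    starts = starts[starts + L <= len(ial.samples) + max_lag]
    if len(starts) == 0:
        raise SyncFailure("record too short for the lag search")
    order = rng.permutation(len(starts))
    lags_found: list[int] = []
    for idx in order:
        if len(lags_found) >= n_windows:
            break
        w0 = int(starts[idx])
        win = sensor.samples[w0:w0 + L]
        if np.ptp(win) <= 0:
            continue
        score = grade_window(normalize_window(win), fs)
        if score.q <= q_min:
            continue
        lags, corr = _norm_xcorr(win, ial.samples, -max_lag, max_lag, w0)
        if len(lags) == 0:
            continue
        best = int(np.argmax(corr))
        if corr[best] < c_min:
            continue
        lag = int(lags[best])
        # heart-rate agreement gate between the two aligned windows
        try:
            hr_s = heart_rate(segment_beats(win - win.mean(), fs), fs)
            ref = ial.samples[w0 + lag:w0 + lag + L]
            hr_i = heart_rate(segment_beats(ref - ref.mean(), fs), fs)
        except (ValueError, TooShortError):
            continue
        if abs(hr_s - hr_i) > HR_AGREEMENT_BPM:
            continue
        lags_found.append(lag)
    if len(lags_found) < 3:
        raise SyncFailure(f"only {len(lags_found)} usable windows for global lag")
    return int(round(float(np.median(lags_found))))


def refine_local_lag(sensor_window: np.ndarray, ial: np.ndarray, start: int,
                     global_lag: int, max_drift: int = MAX_DRIFT_SAMPLES,
                     c_min: float = 0.5) -> Optional[tuple[int, float]]:
    """Per-window lag within ``global_lag +- max_drift``.

    Returns ``(local_lag, correlation)``, or ``None`` when the
    correlation peak is below ``c_min`` (window unalignable — e.g. pure
    noise or a span deleted from one stream).
    """
    lags, corr = _norm_xcorr(np.asarray(sensor_window, dtype=float), ial,
                             global_lag - max_drift, global_lag + max_drift,
                             start)
    if len(lags) == 0:
        return None
    best = int(np.argmax(corr))
    if corr[best] < c_min:
        return None
    return int(lags[best]), float(corr[best])


# --------------------------------------------------------------------------
# paired database
# --------------------------------------------------------------------------

def _prep_streams(ds: PatientDataset, fspec: FilterSpec
                  ) -> tuple[WaveformRecord, list[WaveformRecord], Optional[float]]:
    """Bandpass both streams; detect and notch HFOV interference.

    The notch (when ventilation interference is detected on any sensor
    channel) is applied to both streams so their in-band content stays
    comparable for correlation.
    """
    ial_f = bandpass_filter(ds.ial, fspec)
    sensors_f = [bandpass_filter(s, fspec) for s in ds.sensors]
    freqs = []
    for s in sensors_f:
        try:
            f_v = detect_hfov(s)
        except TooShortError:
            f_v = None
        if f_v is not None:
            freqs.append(f_v)
    # demand agreement: interference from the ventilator reaches every
    # channel, a single-channel detection is treated as a false alarm
    f_v = float(np.median(freqs)) if len(freqs) >= 2 else None
    if f_v is not None:
        ial_f = notch_filter(ial_f, f_v)
        sensors_f = [notch_filter(s, f_v) for s in sensors_f]
    return ial_f, sensors_f, f_v


def _window_truth(ial_raw: np.ndarray, annotations: Sequence[BeatAnnotation],
                  lo: int, hi: int) -> tuple[Optional[BPTriplet], list[BeatAnnotation]]:
    """Mean per-beat BP over complete beats inside [lo, hi)."""
    inside = [b for b in annotations if b.start >= lo and b.end <= hi]
    if len(inside) < 3:
        return None, inside
    trips = [extract_bp_truth(ial_raw, b) for b in inside]
    arr = np.array([[t.sbp, t.dbp, t.map] for t in trips])
    m = arr.mean(axis=0)
    return BPTriplet(sbp=float(m[0]), dbp=float(m[1]), map=float(m[2])), inside


def build_paired_database(cohort: Sequence[PatientDataset],
                          window: WindowSpec = WindowSpec(),
                          rule: ExclusionRule = ExclusionRule(),
                          fspec: FilterSpec = FilterSpec(),
                          seed: int = 0,
                          sync_seed: int = 0,
                          max_per_patient: int = MAX_WINDOWS_PER_PATIENT,
                          ) -> tuple[list[PairedWindow], list[ExclusionLogEntry], dict]:
    """Run conditioning, quality gating and synchronization for a cohort
    and emit the paired training database.

    Per patient: both streams are bandpassed (and notch-filtered when
    ventilation interference is detected); the global lag is estimated;
    each analysis window selects the best of the four sensor channels,
    is aligned to its first beat onset, locally re-synchronized, graded
    against its arterial reference, and gated by the exclusion rules.
    Patients contributing more than ``max_per_patient`` windows are
    randomly subsampled to that cap (seeded); patients with fewer than
    10 usable windows are excluded entirely.

    Returns (paired windows, exclusion log, per-patient sync info).
    """
    rng = np.random.default_rng(seed)
    out: list[PairedWindow] = []
    log: list[ExclusionLogEntry] = []
    sync_info: dict[str, dict] = {}
    for ds in cohort:
        pid = ds.meta.patient_id
        fs = ds.ial.fs_hz
        L = window.length_samples(fs)
        ial_f, sensors_f, f_v = _prep_streams(ds, fspec)
        try:
            g_lag = estimate_global_lag(sensors_f[0], ial_f, seed=sync_seed)
        except SyncFailure:
            # channel 0 may be the poorly coupled one; try the others
            g_lag = None
            for s in sensors_f[1:]:
                try:
                    g_lag = estimate_global_lag(s, ial_f, seed=sync_seed)
                    break
                except SyncFailure:
                    continue
            if g_lag is None:
                sync_info[pid] = {"status": "sync_failed"}
                continue
        annotations = segment_beats(ial_f.samples, fs)
        kept: list[PairedWindow] = []
        for w0 in window.starts(len(sensors_f[0].samples), fs):
            w0 = int(w0)
            wid = f"{pid}:w{w0}"
            try:
                ch, _ = select_best_channel(
                    [s.samples[w0:w0 + L] for s in sensors_f], fs)
            except NoUsableChannelError:
                log.append(ExclusionLogEntry(wid, pid, 0.0, None, None,
                                             "drop", "no_usable_channel"))
                continue
            chan = sensors_f[ch].samples
            # align the window to its first beat onset for a deterministic phase
            seg = chan[w0:w0 + L]
            sb = segment_beats(seg - seg.mean(), fs)
            if not sb or w0 + sb[0].start + L > len(chan):
                log.append(ExclusionLogEntry(wid, pid, 0.0, None, None,
                                             "drop", "no_beats"))
                continue
            a0 = w0 + sb[0].start
            crop = chan[a0:a0 + L]
            loc = refine_local_lag(crop, ial_f.samples, a0, g_lag)
            if loc is None:
                log.append(ExclusionLogEntry(wid, pid, 0.0, None, None,
                                             "drop", "unalignable"))
                continue
            lag, _align_c = loc
            lo, hi = a0 + lag, a0 + lag + L
            truth, in_beats = _window_truth(ds.ial.samples, annotations, lo, hi)
            if truth is None or len(in_beats) < 5:
                log.append(ExclusionLogEntry(wid, pid, 0.0, None, None,
                                             "drop", "too_few_beats"))
                continue
            snr = compute_snr(ial_f.samples,
                              [b.start for b in in_beats],
                              [b.end for b in in_beats])
            try:
                norm = normalize_window(crop)
                ref = normalize_window(ial_f.samples[lo:hi])
            except Exception:
                log.append(ExclusionLogEntry(wid, pid, 0.0, None, snr,
                                             "drop", "degenerate"))
                continue
            score = grade_window(norm, fs, reference_window=ref)
            keep, reason = apply_exclusions(truth, snr, score, rule)
            log.append(ExclusionLogEntry(wid, pid, score.q, score.r, snr,
                                         "keep" if keep else "drop", reason))
            if keep:
                kept.append(PairedWindow(wid, pid, norm, truth,
                                         ds.meta.age_days, ds.meta.weight_kg,
                                         score, channel=ch, local_lag=lag))
        if len(kept) < MIN_WINDOWS_PER_PATIENT:
            sync_info[pid] = {"status": "excluded_too_few_windows",
                              "n_windows": len(kept), "global_lag": g_lag}
            continue
        if len(kept) > max_per_patient:
            sel = rng.choice(len(kept), size=max_per_patient, replace=False)
            kept = [kept[i] for i in sorted(sel)]
        sync_info[pid] = {"status": "ok", "n_windows": len(kept),
                          "global_lag": g_lag, "hfov_hz": f_v}
        out.extend(kept)
    return out, log, sync_info
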