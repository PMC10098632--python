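"""Synthetic neonatal hemodynamics cohort.

Generates paired recordings that emulate a bedside study in which an
invasive arterial line (IAL, mmHg) and an unscaled 4-channel capacitive
pulse sensor record the same patient simultaneously at 125 Hz. The
simulator provides exact per-beat ground truth (SBP/DBP/MAP), a known
inter-stream lag, and the noise structure the estimation pipeline is
designed to defeat: baseline drift, respiratory modulation, broadband
noise, optional high-frequency-oscillatory-ventilation (HFOV)
interference, motion-artifact bursts, and sensor-stream dropouts.

Blood pressure is encoded in the *shape* of the pulse, not only its
amplitude: the relative dicrotic-bump height rises with SBP and the
end-diastolic shelf rises with DBP. This is what makes calibration-free
inference from the normalized (amplitude-less) waveform possible, and it
mirrors the physiological fact that arterial waveform morphology carries
pressure information.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PatientMeta",
    "HfovConfig",
    "MotionConfig",
    "NoiseConfig",
    "SimulationConfig",
    "WaveformRecord",
    "GroundTruth",
    "PatientDataset",
    "simulate_beat_template",
    "simulate_patient",
    "simulate_cohort",
]

#: Study inclusion bounds on weight (kg).
WEIGHT_MIN_KG = 0.4
WEIGHT_MAX_KG = 5.0

#: Cohort sampling range actually observed in the emulated study population.
COHORT_WEIGHT_RANGE = (0.55, 4.85)
COHORT_GA_RANGE = (24.14, 41.29)


class InvalidBPError(ValueError):
    """Raised when a requested beat has sbp <= dbp or non-positive pressure."""


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientMeta:
    """Demographics for one simulated patient.

    ``ga_class`` follows the WHO prematurity bands: extremely preterm
    (EPT, < 28 weeks), moderately preterm (MPT, 28-37 weeks), full term
    (FT, >= 38 weeks).
    """

    patient_id: str
    age_days: float
    weight_kg: float
    ga_weeks: float
    sex: str  # "female" | "male"

    def __post_init__(self) -> None:
        if not (WEIGHT_MIN_KG <= self.weight_kg <= WEIGHT_MAX_KG):
            raise ValueError(
                f"weight_kg={self.weight_kg} outside study range "
                f"[{WEIGHT_MIN_KG}, {WEIGHT_MAX_KG}]"
            )
        if self.age_days < 0:
            raise ValueError("age_days must be non-negative")
        if self.ga_weeks <= 0:
            raise ValueError("ga_weeks must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")

    @property
    def ga_class(self) -> str:
        if self.ga_weeks < 28:
            return "EPT"
        if self.ga_weeks < 38:
            return "MPT"
        return "FT"


@dataclass(frozen=True)
class HfovConfig:
    enabled: bool = False
    freq_hz: float = 10.0
    amp: float = 1.0  # relative to mean pulse amplitude


@dataclass(frozen=True)
class MotionConfig:
    rate_per_min: float = 0.5
    duration_s: float = 2.0
    amp: float = 4.0  # relative to mean pulse amplitude


@dataclass(frozen=True)
class NoiseConfig:
    """Additive disturbance model for the sensor channels.

    Amplitudes are expressed relative to the channel's mean pulse
    amplitude (gain x pulse pressure), so a value of 1.0 means a
    disturbance as large as the pulse itself.
    """

    baseline_drift_amp: float = 0.5
    respiratory_freq_hz: float = 0.6
    respiratory_amp: float = 0.10
    hf_noise_sd: float = 0.05
    hfov: HfovConfig = field(default_factory=HfovConfig)
    motion_bursts: MotionConfig = field(default_factory=MotionConfig)
    #: respiratory swing of the arterial baseline itself, in mmHg
    ial_respiratory_amp_mmhg: float = 1.0
    #: transducer measurement noise on the arterial line, in mmHg
    ial_noise_sd_mmhg: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to synthesize one patient's paired recording."""

    fs_hz: float = 125.0
    duration_s: float = 600.0
    # heart rate: mean, slow per-beat random-walk step (bpm), and
    # independent beat-to-beat period jitter (samples) emulating normal
    # heart-rate variability
    hr_bpm: float = 145.0
    hr_walk_sd: float = 0.5
    hr_jitter_samples: float = 2.0
    hr_bounds: tuple[float, float] = (100.0, 200.0)
    # BP trajectory: per-patient baselines and bounded random walk per beat
    sbp_baseline: float = 65.0
    dbp_baseline: float = 40.0
    bp_walk_sd: float = 0.3
    bp_walk_bound: float = 8.0
    # sensor transform: per-channel affine gain/offset, optional saturation
    gains: tuple[float, ...] = (1.3, 0.7, 1.8, 0.55)
    offsets: tuple[float, ...] = (120.0, -40.0, 300.0, 15.0)
    saturation: bool = False
    saturation_scale: float = 3.0  # tanh knee, in pulse-amplitude units
    # per-channel coupling quality: noise is divided by this multiplier
    channel_coupling: tuple[float, ...] = (1.0, 0.5, 0.25, 0.12)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    # alignment convention: sensor index i corresponds to IAL index i + lag
    lag_samples: int = 0
    # segments deleted from the sensor stream: (start_s, duration_s)
    dropouts: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.fs_hz / 2.0
        top = max(
            self.noise.respiratory_freq_hz,
            self.noise.hfov.freq_hz if self.noise.hfov.enabled else 0.0,
        )
        if self.fs_hz <= 2.0 * top:
            raise ConfigError(f"fs_hz={self.fs_hz} below Nyquist for {top} Hz content")
        if self.noise.hfov.enabled and not (5.0 < self.noise.hfov.freq_hz < 20.0):
            raise ConfigError("HFOV frequency must lie in (5, 20) Hz")
        if self.noise.hfov.freq_hz >= nyq:
            raise ConfigError("HFOV frequency above Nyquist")
        for name in ("baseline_drift_amp", "respiratory_amp", "hf_noise_sd"):
            if getattr(self.noise, name) < 0:
                raise ConfigError(f"noise.{name} must be >= 0")
        if len(self.gains) != 4 or len(self.offsets) != 4 or len(self.channel_coupling) != 4:
            raise ConfigError("sensor transform must specify exactly 4 channels")
        if self.sbp_baseline <= self.dbp_baseline:
            raise ConfigError("sbp_baseline must exceed dbp_baseline")
        deleted = sum(d for _, d in self.dropouts)
        if deleted > 0.5 * self.duration_s:
            raise ConfigError("dropouts delete more than 50% of the stream")


@dataclass
class WaveformRecord:
    """One uniformly sampled channel.

    ``source`` is ``"IAL"`` (mmHg) or ``"sensor_ch0"``..``"sensor_ch3"``
    (arbitrary units).
    """

    patient_id: str
    source: str
    fs_hz: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.source == "IAL" and not np.all(np.isfinite(self.samples)):
            raise ValueError("IAL samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs_hz


@dataclass
class GroundTruth:
    """Per-beat bookkeeping emitted by the simulator.

    Beat spans are half-open ``[start, end)`` sample indices into the IAL
    record; ``map_mmhg`` is the time-average of the clean pressure over
    the span. ``true_lag_samples`` uses the convention that sensor sample
    ``i`` lines up with IAL sample ``i + lag``.
    """

    beat_starts: np.ndarray
    beat_ends: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    map_mmhg: np.ndarray
    true_lag_samples: int

    def __post_init__(self) -> None:
        for a in ("beat_starts", "beat_ends", "sbp_mmhg", "dbp_mmhg", "map_mmhg"):
            setattr(self, a, np.asarray(getattr(self, a)))
        if np.any(self.dbp_mmhg >= self.map_mmhg) or np.any(self.map_mmhg >= self.sbp_mmhg):
            raise ValueError("ground truth must satisfy dbp < map < sbp per beat")
        if np.any(np.diff(self.beat_starts) <= 0) or np.any(self.beat_ends[:-1] > self.beat_starts[1:]):
            raise ValueError("beats must be ordered and non-overlapping")

    @property
    def n_beats(self) -> int:
        return len(self.beat_starts)


@dataclass
class PatientDataset:
    """One patient's complete simulated record."""

    meta: PatientMeta
    ial: WaveformRecord
    sensors: list[WaveformRecord]
    truth: GroundTruth
    config: SimulationConfig


# --------------------------------------------------------------------------
# beat morphology
# --------------------------------------------------------------------------

def _shape_params(sbp: float, dbp: float) -> tuple[float, float, float, float, float]:
    """Morphology parameters as smooth monotone functions of pressure.

    Returns (systolic peak fraction, decay constant, notch center,
    notch height, end-diastolic level), all in normalized beat units.
    """
    ts = float(np.clip(0.14 + 0.0020 * (dbp - 20.0), 0.08, 0.38))
    tau = 0.35
    tn = ts + 0.22
    h = float(np.clip(0.04 + 0.0050 * (sbp - 38.0), 0.02, 0.30))
    s_end = float(np.clip(0.04 + 0.0050 * (dbp - 15.0), 0.02, 0.40))
    return ts, tau, tn, h, s_end


def simulate_beat_template(sbp: float, dbp: float, beat_len: int) -> np.ndarray:
    """One arterial beat: fast systolic upstroke, exponential diastolic
    decay, Gaussian dicrotic bump.

    The returned array has exactly ``max == sbp`` and ``min == dbp``.
    The relative dicrotic-bump height grows with SBP and the
    end-diastolic shelf with DBP, so the normalized shape is informative
    about absolute pressure.
    """
    if sbp <= dbp or dbp <= 0:
        raise InvalidBPError(f"need sbp > dbp > 0, got sbp={sbp}, dbp={dbp}")
    if beat_len < 10:
        raise ValueError("beat_len must be >= 10 samples")

    ts, tau, tn, h, s_end = _shape_params(sbp, dbp)
    x = np.arange(beat_len) / beat_len
    s = np.empty(beat_len)
    up = x < ts
    s[up] = np.sin(np.pi * x[up] / (2.0 * ts))
    xd = x[~up]
    decay = (np.exp(-(xd - ts) / tau) - np.exp(-(1.0 - ts) / tau)) / (
        1.0 - np.exp(-(1.0 - ts) / tau)
    )
    s[~up] = s_end + (1.0 - s_end) * decay
    s[~up] += h * np.exp(-0.5 * ((xd - tn) / 0.035) ** 2)
    # exact amplitude contract
    s = (s - s.min()) / (s.max() - s.min())
    return dbp + (sbp - dbp) * s


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def _bounded_walk(rng: np.random.Generator, n: int, start: float, step_sd: float,
                  lo: float, hi: float) -> np.ndarray:
    """Gaussian random walk reflected at [lo, hi]."""
    steps = rng.normal(0.0, step_sd, size=n)
    out = np.empty(n)
    v = start
    for i in range(n):
        v = v + steps[i]
        if v > hi:
            v = 2 * hi - v
        elif v < lo:
            v = 2 * lo - v
        out[i] = v
    return out


def _beat_sequence(config: SimulationConfig, rng: np.random.Generator,
                   n_samples: int) -> tuple[np.ndarray, GroundTruth]:
    """Clean arterial pressure trace plus exact per-beat bookkeeping."""
    fs = config.fs_hz
    # generous upper bound on beat count (jitter can shorten beats)
    max_beats = int(1.2 * np.ceil(n_samples / (fs * 60.0 / config.hr_bounds[1]))) + 10
    hr = _bounded_walk(rng, max_beats, config.hr_bpm, config.hr_walk_sd,
                       *config.hr_bounds)
    sbp = _bounded_walk(rng, max_beats, config.sbp_baseline, config.bp_walk_sd,
                        config.sbp_baseline - config.bp_walk_bound,
                        config.sbp_baseline + config.bp_walk_bound)
    dbp = _bounded_walk(rng, max_beats, config.dbp_baseline, config.bp_walk_sd,
                        config.dbp_baseline - config.bp_walk_bound,
                        config.dbp_baseline + config.bp_walk_bound)
    # keep a physiological pulse pressure
    dbp = np.minimum(dbp, sbp - 10.0)

    jitter = rng.normal(0.0, config.hr_jitter_samples, size=max_beats)
    pressure = np.empty(n_samples)
    starts, ends, sbps, dbps = [], [], [], []
    pos = 0
    k = 0
    while pos < n_samples:
        beat_len = max(int(round(fs * 60.0 / hr[k] + jitter[k])), 12)
        beat = simulate_beat_template(sbp[k], dbp[k], beat_len)
        end = min(pos + beat_len, n_samples)
        pressure[pos:end] = beat[: end - pos]
        # only complete beats followed by at least one sample (needed to
        # close the trapezoidal MAP integral) enter ground truth
        if end - pos == beat_len and end < n_samples:
            starts.append(pos)
            ends.append(end)
            sbps.append(sbp[k])
            dbps.append(dbp[k])
        pos = end
        k += 1
    maps = [float(np.trapezoid(pressure[s:e + 1]) / (e - s))
            for s, e in zip(starts, ends)]
    truth = GroundTruth(
        beat_starts=np.array(starts, dtype=int),
        beat_ends=np.array(ends, dtype=int),
        sbp_mmhg=np.array(sbps),
        dbp_mmhg=np.array(dbps),
        map_mmhg=np.array(maps),
        true_lag_samples=config.lag_samples,
    )
    return pressure, truth


def _lagged(base: np.ndarray, lag: int) -> np.ndarray:
    """sensor[i] = base[i + lag], edge-padded."""
    n = len(base)
    idx = np.clip(np.arange(n) + lag, 0, n - 1)
    return base[idx]


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        low: float, high: float) -> np.ndarray:
    """Unit-RMS noise restricted to [low, high] Hz via FFT masking."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    out = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _sensor_channel(base: np.ndarray, resp_base: np.ndarray, ch: int,
                    config: SimulationConfig, rng: np.random.Generator,
                    pulse_amp: float) -> np.ndarray:
    fs = config.fs_hz
    n = len(base)
    t = np.arange(n) / fs
    gain = config.gains[ch]
    unit = abs(gain) * pulse_amp  # disturbance scale: one pulse amplitude
    y = gain * base
    if config.saturation:
        center = np.median(y)
        knee = config.saturation_scale * unit
        y = center + knee * np.tanh((y - center) / knee)
    y = y + config.offsets[ch]

    nz = config.noise
    scale = unit / config.channel_coupling[ch]
    if nz.baseline_drift_amp > 0:
        drift = _band_limited_noise(rng, n, fs, 0.0, 0.05)
        y += nz.baseline_drift_amp * scale * drift
    if nz.respiratory_amp > 0:
        # breathing moves chest and limb together: the sensor sees the
        # same (lagged) respiratory phase as the arterial line
        y += nz.respiratory_amp * scale * resp_base
    if nz.hf_noise_sd > 0:
        y += nz.hf_noise_sd * scale * rng.normal(size=n)
    if nz.hfov.enabled:
        phase = rng.uniform(0, 2 * np.pi)
        y += nz.hfov.amp * unit * np.sin(2 * np.pi * nz.hfov.freq_hz * t + phase)
    mb = nz.motion_bursts
    if mb.rate_per_min > 0:
        n_bursts = rng.poisson(mb.rate_per_min * (n / fs) / 60.0)
        burst_len = max(int(mb.duration_s * fs), 1)
        for _ in range(n_bursts):
            start = rng.integers(0, max(n - burst_len, 1))
            burst = _band_limited_noise(rng, burst_len, fs, 0.5, 15.0)
            y[start:start + burst_len] += mb.amp * unit * burst
            y[start:start + burst_len] += mb.amp * unit * rng.uniform(-0.5, 0.5)
    return y


def simulate_patient(meta: PatientMeta, config: SimulationConfig) -> PatientDataset:
    """Simulate one paired IAL / 4-channel sensor recording.

    The sensor channels are monotone (affine, optionally mildly
    saturating) transforms of the lagged arterial pressure plus
    channel-specific noise; the IAL channel is the clean pressure plus a
    small respiratory swing and transducer noise. Ground truth refers to
    the clean pressure, so per-beat extrema are exact by construction.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    pressure, truth = _beat_sequence(config, rng, n)

    t = np.arange(n) / config.fs_hz
    nz = config.noise
    resp_phase = rng.uniform(0, 2 * np.pi)
    resp_base = np.sin(2 * np.pi * nz.respiratory_freq_hz * t + resp_phase)
    ial_samples = pressure.copy()
    if nz.ial_respiratory_amp_mmhg > 0:
        ial_samples += nz.ial_respiratory_amp_mmhg * resp_base
    if nz.ial_noise_sd_mmhg > 0:
        ial_samples += nz.ial_noise_sd_mmhg * rng.normal(size=n)
    ial = WaveformRecord(meta.patient_id, "IAL", config.fs_hz, ial_samples)

    pulse_amp = config.sbp_baseline - config.dbp_baseline
    base = _lagged(pressure, config.lag_samples)
    resp_lagged = _lagged(resp_base, config.lag_samples)
    keep = np.ones(n, dtype=bool)
    for start_s, dur_s in config.dropouts:
        i0 = int(round(start_s * config.fs_hz))
        i1 = i0 + int(round(dur_s * config.fs_hz))
        keep[i0:i1] = False
    sensors = []
    for ch in range(4):
        y = _sensor_channel(base, resp_lagged, ch, config, rng, pulse_amp)
        sensors.append(WaveformRecord(meta.patient_id, f"sensor_ch{ch}",
                                      config.fs_hz, y[keep]))
    return PatientDataset(meta=meta, ial=ial, sensors=sensors, truth=truth,
                          config=config)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def _draw_meta(rng: np.random.Generator, pid: str, ga_class: str) -> PatientMeta:
    lo, hi = COHORT_GA_RANGE
    if ga_class == "EPT":
        ga = rng.uniform(lo, 28.0)
    elif ga_class == "MPT":
        ga = rng.uniform(28.0, 38.0)
    else:
        ga = rng.uniform(38.0, hi)
    w_lo, w_hi = COHORT_WEIGHT_RANGE
    weight = float(np.clip(0.25 * ga - 5.3 + rng.normal(0, 0.45), w_lo, w_hi))
    age = float(np.clip(round(np.exp(rng.normal(np.log(17.0), 1.0))), 1, 150))
    sex = "male" if rng.uniform() < 0.605 else "female"
    return PatientMeta(patient_id=pid, age_days=age, weight_kg=weight,
                       ga_weeks=float(ga), sex=sex)


def _patient_config(base: SimulationConfig, rng: np.random.Generator,
                    meta: PatientMeta) -> SimulationConfig:
    """Per-patient baselines: BP rises with weight, plus idiosyncrasy."""
    sbp0 = float(np.clip(45.0 + 7.0 * meta.weight_kg + rng.normal(0, 4.0), 40.0, 91.0))
    dbp0 = float(np.clip(22.0 + 5.0 * meta.weight_kg + rng.normal(0, 3.0), 19.0, sbp0 - 12.0))
    hr = float(rng.uniform(115.0, 175.0))
    lag = int(rng.integers(-250, 251)) if base.lag_samples == 0 else base.lag_samples
    gains = tuple(float(rng.uniform(0.5, 2.0)) for _ in range(4))
    offsets = tuple(float(rng.uniform(-200.0, 400.0)) for _ in range(4))
    return replace(base, sbp_baseline=sbp0, dbp_baseline=dbp0, hr_bpm=hr,
                   lag_samples=lag, gains=gains, offsets=offsets,
                   seed=int(rng.integers(2**31)))


def simulate_cohort(n_patients: int,
                    config: Optional[SimulationConfig] = None,
                    seed: int = 0,
                    ga_fractions: Sequence[float] = (0.19, 0.47, 0.34),
                    ) -> list[PatientDataset]:
    """Simulate a cohort spanning the study's demographic ranges.

    Gestational-age strata (EPT/MPT/FT) are allocated by ``ga_fractions``
    with at least one patient per stratum whenever ``n_patients >= 3``;
    weight tracks gestational age; per-patient BP baselines rise with
    weight so the demographic covariates are genuinely informative.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    classes = ["EPT", "MPT", "FT"]
    if n_patients >= 3:
        counts = [max(1, int(round(f * n_patients))) for f in ga_fractions]
        while sum(counts) > n_patients:
            counts[int(np.argmax(counts))] -= 1
        while sum(counts) < n_patients:
            counts[int(np.argmin(counts))] += 1
    else:
        counts = [0, n_patients, 0]
    assignment = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(assignment)

    cohort = []
    for i, ga_class in enumerate(assignment):
        meta = _draw_meta(rng, f"P{i:03d}", ga_class)
        pconf = _patient_config(config, rng, meta)
        cohort.append(simulate_patient(meta, pconf))
    return cohort
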