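"""Simulator contracts: beat morphology, ground-truth bookkeeping,
spectral content, lag encoding, cohort demographics."""

import numpy as np
import pytest
from scipy import signal

from neobp.simulate import (ConfigError, HfovConfig, InvalidBPError,
                            PatientMeta, SimulationConfig,
                            simulate_beat_template, simulate_cohort,
                            simulate_patient)
from .conftest import FS, clean_noise


class TestBeatTemplate:
    def test_amplitude_contract(self):
        beat = simulate_beat_template(65, 40, 50)
        assert beat.max() == 65
        assert beat.min() == 40

    def test_mean_strictly_between_extremes(self):
        beat = simulate_beat_template(65, 40, 50)
        assert 40 < beat.mean() < 65

    def test_beat_length_from_heart_rate(self):
        # 150 bpm at 125 Hz -> 50-sample beats
        assert int(round(FS * 60 / 150)) == 50

    def test_single_primary_peak(self):
        beat = simulate_beat_template(80, 45, 60)
        peaks, _ = signal.find_peaks(beat, prominence=0.3 * np.ptp(beat))
        assert len(peaks) == 1

    def test_secondary_inflection_present(self):
        # curvature reversal on the descending limb (dicrotic bump)
        beat = simulate_beat_template(80, 45, 80)
        descent = beat[np.argmax(beat):]
        d2 = np.diff(descent, 2)
        assert d2.max() > 0

    def test_invalid_bp_raises(self):
        with pytest.raises(InvalidBPError):
            simulate_beat_template(40, 65, 50)
        with pytest.raises(InvalidBPError):
            simulate_beat_template(40, 40, 50)


class TestSimulatePatient:
    def test_clean_per_beat_extrema_exact(self, clean_patient):
        t = clean_patient.truth
        x = clean_patient.ial.samples
        for i in range(t.n_beats):
            s, e = t.beat_starts[i], t.beat_ends[i]
            assert x[s:e].max() == t.sbp_mmhg[i]
            assert x[s:e].min() == t.dbp_mmhg[i]

    def test_map_is_time_average(self, clean_patient):
        # independent numeric time-average (trapezoid over the closed span)
        t = clean_patient.truth
        x = clean_patient.ial.samples
        for i in range(0, t.n_beats, 7):
            s, e = t.beat_starts[i], t.beat_ends[i]
            area = (x[s] + x[e]) / 2 + np.sum(x[s + 1:e])
            assert t.map_mmhg[i] == pytest.approx(area / (e - s), rel=1e-12)

    def test_bp_ordering_every_beat(self, clean_patient, noisy_patient):
        for ds in (clean_patient, noisy_patient):
            t = ds.truth
            assert np.all(t.dbp_mmhg < t.map_mmhg)
            assert np.all(t.map_mmhg < t.sbp_mmhg)

    def test_seed_determinism_bit_identical(self, meta):
        cfg = SimulationConfig(duration_s=30.0, seed=99)
        a = simulate_patient(meta, cfg)
        b = simulate_patient(meta, cfg)
        assert np.array_equal(a.ial.samples, b.ial.samples)
        for sa, sb in zip(a.sensors, b.sensors):
            assert np.array_equal(sa.samples, sb.samples)
        assert np.array_equal(a.truth.sbp_mmhg, b.truth.sbp_mmhg)

    def test_sensor_correlates_with_ial_after_bandpass(self, noisy_patient):
        from neobp.preprocess import bandpass_filter
        lag = noisy_patient.truth.true_lag_samples
        s = bandpass_filter(noisy_patient.sensors[0]).samples
        a = bandpass_filter(noisy_patient.ial).samples
        r = np.corrcoef(s[:-lag], a[lag:])[0, 1]
        assert r > 0.9

    def test_hfov_spectral_line(self, meta):
        nz = clean_noise(hfov=HfovConfig(enabled=True, freq_hz=10.0, amp=1.0),
                         hf_noise_sd=0.02)
        ds = simulate_patient(meta, SimulationConfig(duration_s=60.0, seed=1,
                                                     noise=nz))
        f, p = signal.periodogram(ds.sensors[0].samples
                                  - ds.sensors[0].samples.mean(), fs=FS)
        above5 = f > 5
        f_peak = f[above5][np.argmax(p[above5])]
        assert f_peak == pytest.approx(10.0, abs=0.2)

    def test_respiratory_spectral_line_in_ial(self, meta):
        nz = clean_noise(ial_respiratory_amp_mmhg=1.5, respiratory_freq_hz=0.5)
        ds = simulate_patient(meta, SimulationConfig(duration_s=120.0, seed=1,
                                                     noise=nz))
        f, p = signal.periodogram(ds.ial.samples - ds.ial.samples.mean(), fs=FS)
        sel = (f > 0.3) & (f < 1.0)
        assert f[sel][np.argmax(p[sel])] == pytest.approx(0.5, abs=0.05)

    def test_noiseless_lag_is_exact_xcorr_peak(self, meta):
        lag = 83
        cfg = SimulationConfig(duration_s=40.0, seed=5, lag_samples=lag,
                               noise=clean_noise())
        ds = simulate_patient(meta, cfg)
        s = ds.sensors[0].samples - np.mean(ds.sensors[0].samples)
        a = ds.ial.samples - np.mean(ds.ial.samples)
        # restrict to the interior to avoid edge-padding effects
        w = s[500:2500]
        corrs = [np.dot(w, a[500 + k:2500 + k]) for k in range(-200, 201)]
        assert range(-200, 201)[int(np.argmax(corrs))] == lag

    def test_dropout_over_half_rejected(self, meta):
        with pytest.raises(ConfigError):
            SimulationConfig(duration_s=10.0, dropouts=((0.0, 6.0),))

    def test_dropouts_shorten_sensor_only(self, meta):
        cfg = SimulationConfig(duration_s=20.0, seed=2,
                               dropouts=((5.0, 1.0),))
        ds = simulate_patient(meta, cfg)
        assert len(ds.ial.samples) == int(20 * FS)
        assert len(ds.sensors[0].samples) == int(19 * FS)


class TestCohort:
    def test_weights_within_study_range(self):
        cohort = simulate_cohort(10, seed=7)
        assert len(cohort) == 10
        for ds in cohort:
            assert 0.55 <= ds.meta.weight_kg <= 4.85

    def test_single_patient_deterministic(self):
        a = simulate_cohort(1, seed=4)[0]
        b = simulate_cohort(1, seed=4)[0]
        assert a.meta == b.meta
        assert np.array_equal(a.ial.samples, b.ial.samples)

    def test_all_ga_strata_present(self):
        cohort = simulate_cohort(30, seed=1)
        classes = {ds.meta.ga_class for ds in cohort}
        assert classes == {"EPT", "MPT", "FT"}

    def test_ga_class_boundaries(self):
        m = lambda ga: PatientMeta("x", 1, 2.0, ga, "female").ga_class
        assert m(27.9) == "EPT"
        assert m(28.0) == "MPT"
        assert m(37.9) == "MPT"
        assert m(38.0) == "FT"

    def test_weight_bounds_enforced(self):
        with pytest.raises(ValueError):
            PatientMeta("x", 1, 5.5, 38.0, "male")
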