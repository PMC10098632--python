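"""Filtering, interference detection, SNR and normalization contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neobp.preprocess import (DegenerateWindowError, FilterSpec, TooShortError,
                              WindowSpec, bandpass_filter,
                              butterworth_bandpass_gain, compute_snr,
                              detect_hfov, normalize_window, notch_filter)
from neobp.simulate import WaveformRecord, simulate_beat_template
from .conftest import FS


def _rec(x, fs=FS):
    return WaveformRecord("t", "sensor_ch0", fs, np.asarray(x, dtype=float))


def _sine(freq, dur, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _pulse_train(dur, fs=FS, sbp=65.0, dbp=40.0, beat_len=50):
    n_beats = int(dur * fs / beat_len) + 1
    beat = simulate_beat_template(sbp, dbp, beat_len)
    return np.tile(beat, n_beats)[: int(dur * fs)]


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass_filter(_rec(np.full(int(60 * FS), 50.0))).samples
        trim = int(5 * FS)
        assert np.all(np.abs(out[trim:-trim]) < 1e-6)

    @pytest.mark.parametrize("freq", [0.5, 2.0, 5.0])
    def test_passband_gain_matches_analytic(self, freq):
        x = _sine(freq, 60)
        out = bandpass_filter(_rec(x)).samples
        trim = int(10 * FS)
        gain = np.std(out[trim:-trim]) / np.std(x[trim:-trim])
        expected = butterworth_bandpass_gain(freq, 0.1, 20.0, order=2,
                                             zero_phase=True)
        assert gain == pytest.approx(expected, rel=0.01)

    def test_stopband_attenuation_bounded_by_analytic(self):
        x = _sine(40.0, 60)
        out = bandpass_filter(_rec(x)).samples
        trim = int(10 * FS)
        bound = butterworth_bandpass_gain(40.0, 0.1, 20.0, order=2)
        rms_ratio = np.std(out[trim:-trim]) / np.std(x[trim:-trim])
        # analytic bound up to the analog/digital (bilinear) response gap
        assert rms_ratio < 1.5 * bound
        assert rms_ratio < 0.1

    def test_linearity(self, rng):
        x = rng.normal(size=int(30 * FS))
        y = rng.normal(size=int(30 * FS))
        fa = bandpass_filter(_rec(2.0 * x + 3.0 * y)).samples
        fb = 2.0 * bandpass_filter(_rec(x)).samples + 3.0 * bandpass_filter(_rec(y)).samples
        assert np.allclose(fa, fb, atol=1e-8)

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            bandpass_filter(_rec(np.ones(20)))


class TestHfovDetection:
    def test_clean_pulse_gives_none(self):
        assert detect_hfov(_rec(_pulse_train(30))) is None

    def test_strong_interference_found(self):
        x = _pulse_train(30) + _sine(10.0, 30, amp=2 * 25.0)
        f = detect_hfov(_rec(x))
        assert f == pytest.approx(10.0, abs=0.2)

    def test_all_zero_gives_none(self):
        assert detect_hfov(_rec(np.zeros(int(20 * FS)))) is None

    def test_short_record_raises(self):
        with pytest.raises(TooShortError):
            detect_hfov(_rec(np.zeros(int(5 * FS))))


class TestNotch:
    def test_removes_target_frequency(self):
        x = _sine(10.0, 30)
        out = notch_filter(_rec(x), 10.0).samples
        trim = int(5 * FS)
        assert np.sqrt(np.mean(out[trim:-trim] ** 2)) <= 0.1 * np.sqrt(
            np.mean(x[trim:-trim] ** 2))

    def test_preserves_distant_frequency(self):
        x = _sine(2.0, 30)
        out = notch_filter(_rec(x), 10.0).samples
        trim = int(5 * FS)
        assert np.sqrt(np.mean(out[trim:-trim] ** 2)) == pytest.approx(
            np.sqrt(np.mean(x[trim:-trim] ** 2)), rel=0.05)

    def test_none_is_identity(self):
        x = _sine(2.0, 10)
        rec = _rec(x)
        assert notch_filter(rec, None) is rec

    def test_out_of_range_frequency_raises(self):
        with pytest.raises(ValueError):
            notch_filter(_rec(_sine(2.0, 10)), 3.0)

    def test_commutes_with_bandpass(self):
        x = _pulse_train(40) + _sine(10.0, 40, amp=10.0)
        a = notch_filter(bandpass_filter(_rec(x)), 10.0).samples
        b = bandpass_filter(notch_filter(_rec(x), 10.0)).samples
        trim = int(5 * FS)
        d = a[trim:-trim] - b[trim:-trim]
        rms_ratio = np.sqrt(np.mean(d**2)) / np.sqrt(np.mean(a[trim:-trim] ** 2))
        assert rms_ratio < 0.02


class TestSnr:
    @staticmethod
    def _boundaries(n, beat_len):
        starts = np.arange(0, n - beat_len, beat_len)
        return starts, starts + beat_len

    def test_noiseless_periodic_is_huge(self):
        x = _pulse_train(20)
        s, e = self._boundaries(len(x), 50)
        assert compute_snr(x, s, e) > 100

    def test_known_power_ratio_recovered(self):
        # signal/noise power ratio 4 -> estimates concentrate in [3, 5]
        x = _pulse_train(60)
        s, e = self._boundaries(len(x), 50)
        p_sig = np.var(np.tile(simulate_beat_template(65, 40, 50), 2))
        estimates = []
        for seed in range(100):
            noise = np.random.default_rng(seed).normal(
                0, np.sqrt(p_sig / 4), size=len(x))
            estimates.append(compute_snr(x + noise, s, e))
        assert 3 < np.mean(estimates) < 5
        assert np.mean([(3 < v < 5) for v in estimates]) > 0.8

    def test_white_noise_below_one(self, rng):
        x = rng.normal(size=int(20 * FS))
        s, e = self._boundaries(len(x), 50)
        assert compute_snr(x, s, e) < 1

    def test_too_few_beats_raises(self):
        x = _pulse_train(2)
        with pytest.raises(TooShortError):
            compute_snr(x, [0, 50], [50, 100])


class TestNormalize:
    def test_simple_triplet(self):
        assert np.array_equal(normalize_window([40.0, 65.0, 40.0]), [0.0, 1.0, 0.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 100), b=st.floats(-500, 500),
           seed=st.integers(0, 10_000))
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=64)
        assert np.array_equal(normalize_window(a * x + b), normalize_window(x))

    def test_idempotent(self, rng):
        x = rng.normal(size=128)
        once = normalize_window(x)
        assert np.array_equal(normalize_window(once), once)

    def test_rank_order_preserved(self, rng):
        x = rng.normal(size=64)
        assert np.array_equal(np.argsort(x), np.argsort(normalize_window(x)))

    def test_constant_window_raises(self):
        with pytest.raises(DegenerateWindowError):
            normalize_window(np.full(16, 3.0))


class TestWindowSpec:
    def test_window_count_arithmetic(self):
        # 60 s stream, 4 s window, 1 s hop -> 57 complete windows
        assert len(WindowSpec().starts(int(60 * FS), FS)) == 57

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(length_s=4.0, hop_s=0.0)
        with pytest.raises(ValueError):
            FilterSpec(low_hz=5.0, high_hz=1.0)
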