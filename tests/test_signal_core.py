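import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tnrkit as tk
from tnrkit.signal_core import FULL_SCALE_DB_SPL

from conftest import RATE, interior_error_db


class TestAudioSignal:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            tk.AudioSignal(np.array([]), RATE)
        with pytest.raises(ValueError):
            tk.AudioSignal(np.array([0.0, np.nan]), RATE)
        with pytest.raises(ValueError):
            tk.AudioSignal(np.zeros(10), 0.0)

    def test_duration(self):
        sig = tk.AudioSignal(np.zeros(8000), RATE)
        assert sig.duration == pytest.approx(0.5)


class TestResample:
    def test_length_scales_by_rate_ratio(self):
        sig = tk.AudioSignal(np.random.default_rng(0).standard_normal(16000), RATE)
        out = tk.resample(sig, 22050.0)
        assert out.rate == 22050.0
        assert abs(out.duration - sig.duration) <= 1.0 / 16000.0
        assert len(out) == 22050

    def test_identity_rate(self):
        sig = tk.AudioSignal(np.ones(100), RATE)
        assert tk.resample(sig, RATE) is sig

    def test_tone_frequency_preserved(self):
        t = np.arange(16000) / RATE
        sig = tk.AudioSignal(np.sin(2 * np.pi * 1000.0 * t), RATE)
        out = tk.resample(sig, 22050.0)
        spectrum = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out), d=1 / 22050.0)
        assert abs(freqs[np.argmax(spectrum)] - 1000.0) < 1.0

    def test_round_trip_correlation(self):
        # band-limited input: white noise low-passed well below both Nyquists
        rng = np.random.default_rng(1)
        from scipy.signal import sosfiltfilt, butter

        sos = butter(6, 6000.0, fs=RATE, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(16000))
        sig = tk.AudioSignal(x, RATE)
        back = tk.resample(tk.resample(sig, 22050.0), RATE)
        n = min(len(back), len(sig))
        corr = np.corrcoef(back.samples[200 : n - 200], sig.samples[200 : n - 200])[0, 1]
        assert corr > 0.999

    def test_invalid_rate(self):
        sig = tk.AudioSignal(np.ones(10), RATE)
        with pytest.raises(ValueError):
            tk.resample(sig, -1.0)


class TestFraming:
    def test_single_frame_boundary(self):
        spec = tk.FrameSpec(80, 40, RATE, "rect")
        frames = tk.frame_signal(tk.AudioSignal(np.ones(80), RATE), spec)
        assert frames.shape == (1, 80)

    def test_frame_count_formula(self, spec5ms):
        sig = tk.AudioSignal(np.zeros(16000), RATE)
        frames = tk.frame_signal(sig, spec5ms)
        assert frames.shape[0] == 1 + (16000 - 80) // 40 == 399

    def test_rect_window_identity(self):
        spec = tk.FrameSpec(8, 4, RATE, "rect")
        frames = tk.frame_signal(tk.AudioSignal(np.ones(16), RATE), spec)
        assert np.all(frames == 1.0)

    def test_too_short_signal(self, spec5ms):
        with pytest.raises(ValueError):
            tk.frame_signal(tk.AudioSignal(np.ones(40), RATE), spec5ms)

    def test_bad_spec(self):
        with pytest.raises(ValueError):
            tk.FrameSpec(80, 0, RATE)
        with pytest.raises(ValueError):
            tk.FrameSpec(80, 81, RATE)


class TestOverlapAdd:
    @pytest.mark.parametrize(
        "spec",
        [
            tk.FrameSpec.from_ms(5.0, 2.5, RATE),  # hann, 50% overlap
            tk.FrameSpec(22, 10, 22050.0, "tukey", 0.5),  # the MCTR grid
        ],
        ids=["hann-50pct", "tukey-hop10"],
    )
    def test_round_trip_noise(self, spec):
        rng = np.random.default_rng(7)
        n = int(spec.rate)
        sig = tk.AudioSignal(rng.standard_normal(n), spec.rate)
        frames = tk.frame_signal(sig, spec)
        out = tk.overlap_add(frames, spec, len(sig))
        assert interior_error_db(sig.samples, out.samples, 2 * spec.frame_len) <= -40.0

    def test_zeros_round_trip(self, spec5ms):
        frames = tk.frame_signal(tk.AudioSignal(np.zeros(1600), RATE), spec5ms)
        out = tk.overlap_add(frames, spec5ms, 1600)
        assert np.all(out.samples == 0.0)

    def test_sine_round_trip_correlation(self, spec5ms):
        t = np.arange(16000) / RATE
        sig = tk.AudioSignal(np.sin(2 * np.pi * 500.0 * t), RATE)
        out = tk.overlap_add(tk.frame_signal(sig, spec5ms), spec5ms, len(sig))
        sl = slice(160, 16000 - 160)
        corr = np.corrcoef(out.samples[sl], sig.samples[sl])[0, 1]
        assert corr > 0.999

    def test_incompatible_frames(self, spec5ms):
        with pytest.raises(ValueError):
            tk.overlap_add(np.zeros((10, 81)), spec5ms)


class TestRms:
    def test_unit_sine(self):
        t = np.arange(16000) / RATE
        assert tk.rms(np.sin(2 * np.pi * 100.0 * t)) == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_zeros(self):
        assert tk.rms(np.zeros(100)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tk.rms(np.array([]))

    @given(c=st.floats(-100.0, 100.0, allow_nan=False))
    @settings(deadline=None, max_examples=25)
    def test_scale_equivariance(self, c):
        x = np.linspace(-1, 1, 64)
        assert tk.rms(c * x) == pytest.approx(abs(c) * tk.rms(x), rel=1e-12, abs=1e-12)


class TestSetLevel:
    def test_convention_60_db_spl(self, speech2s):
        out = tk.set_level(speech2s, 60.0)
        assert tk.rms(out) == pytest.approx(10 ** ((60.0 - FULL_SCALE_DB_SPL) / 20.0))
        assert tk.rms(out) == pytest.approx(0.01)

    def test_idempotent(self, speech2s):
        once = tk.set_level(speech2s, 65.0)
        twice = tk.set_level(once, 65.0)
        np.testing.assert_allclose(twice.samples, once.samples, rtol=1e-12)

    def test_six_db_doubles_rms(self, speech2s):
        low = tk.set_level(speech2s, 60.0)
        high = tk.set_level(speech2s, 66.02)
        assert tk.rms(high) / tk.rms(low) == pytest.approx(2.0, rel=1e-3)

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError):
            tk.set_level(tk.AudioSignal(np.zeros(100), RATE), 60.0)


class TestGainFilter:
    def test_flat_table_is_delayed_identity(self):
        rng = np.random.default_rng(3)
        sig = tk.AudioSignal(rng.standard_normal(8000), RATE)
        table = tk.GainTable(np.array([100.0, 4000.0]), np.array([0.0, 0.0]))
        out = tk.apply_gain_filter(sig, table, n_taps=513)
        delay = 256
        err = tk.rms(out.samples[delay:] - sig.samples[: 8000 - delay]) / tk.rms(sig)
        assert 20 * np.log10(err) <= -40.0

    def test_flat_6db_doubles_rms(self, speech2s):
        table = tk.GainTable(np.array([100.0, 7000.0]), np.array([6.02, 6.02]))
        out = tk.apply_gain_filter(speech2s, table)
        assert tk.rms(out) / tk.rms(speech2s) == pytest.approx(2.0, rel=0.02)

    def test_probe_tone_gain(self):
        t = np.arange(16000) / RATE
        probe = tk.AudioSignal(np.sin(2 * np.pi * 4000.0 * t), RATE)
        table = tk.GainTable(np.array([1000.0, 4000.0]), np.array([0.0, 20.0]))
        out = tk.apply_gain_filter(probe, table, n_taps=513)
        gain_db = 20 * np.log10(tk.rms(out.samples[1000:]) / tk.rms(probe.samples[1000:]))
        assert gain_db == pytest.approx(20.0, abs=1.0)

    def test_even_taps_rejected(self, speech2s):
        table = tk.GainTable(np.array([100.0, 4000.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            tk.apply_gain_filter(speech2s, table, n_taps=512)

    def test_gain_table_validation(self):
        with pytest.raises(ValueError):
            tk.GainTable(np.array([100.0, 100.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            tk.GainTable(np.array([100.0]), np.array([0.0, 1.0]))


class TestLatency:
    def test_five_ms_fifty_percent(self, spec5ms):
        assert tk.algorithmic_latency(spec5ms) == pytest.approx(7.5)

    def test_no_overlap_equals_frame(self):
        spec = tk.FrameSpec(80, 80, RATE)
        assert tk.algorithmic_latency(spec) == pytest.approx(5.0)

    def test_twenty_ms_fifty_percent(self):
        spec = tk.FrameSpec.from_ms(20.0, 10.0, RATE)
        assert tk.algorithmic_latency(spec) == pytest.approx(30.0)


class TestWavIO:
    @pytest.mark.parametrize("subtype", ["float", "pcm16"])
    def test_round_trip(self, tmp_path, subtype, speech2s):
        path = tmp_path / f"sig_{subtype}.wav"
        tk.write_wav(path, speech2s, subtype=subtype)
        back = tk.read_wav(path)
        assert back.rate == speech2s.rate
        tol = 1e-6 if subtype == "float" else 1.0 / 32768.0
        np.testing.assert_allclose(back.samples, speech2s.samples, atol=tol)
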