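import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tnrkit as tk
from tnrkit.tf_features import erb_number

from conftest import RATE


class TestErbScale:
    def test_erb_number_1khz(self):
        # E(1000) = 21.4*log10(5.37) Cams
        assert erb_number(1000.0) == pytest.approx(21.4 * np.log10(5.37), abs=1e-6)
        assert erb_number(1000.0) == pytest.approx(15.62, abs=0.01)

    def test_inverse(self):
        freqs = np.array([50.0, 500.0, 4000.0, 8000.0])
        np.testing.assert_allclose(tk.erb_number_to_hz(erb_number(freqs)), freqs, rtol=1e-10)


class TestBuildBank:
    def test_default_layout(self, bank64):
        assert bank64.n_channels == 64
        assert bank64.center_freqs[0] == pytest.approx(50.0)
        assert bank64.center_freqs[-1] == pytest.approx(8000.0)
        # equal spacing on the Cam scale
        cams = erb_number(bank64.center_freqs)
        np.testing.assert_allclose(np.diff(cams), np.diff(cams)[0], rtol=1e-6)

    def test_single_peak_per_channel(self, bank64):
        freqs = np.fft.rfftfreq(bank64.fft_size, d=1.0 / bank64.rate)
        for i in range(0, 64, 9):
            k = np.argmax(bank64.bin_weights[i])
            # peak bin nearest to the center frequency
            assert abs(freqs[k] - bank64.center_freqs[i]) <= (freqs[1] - freqs[0])

    def test_degenerate_single_channel(self):
        bank = tk.build_bank(n_channels=1, f_lo=100.0, f_hi=4000.0)
        assert bank.center_freqs[0] == pytest.approx(100.0)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            tk.build_bank(f_hi=9000.0, rate=16000.0)


class TestExtractFeatures:
    def test_silence_gives_zeros(self, bank64, spec5ms):
        sig = tk.AudioSignal(np.zeros(1600), RATE)
        feats = tk.extract_features(sig, bank64, spec5ms)
        assert np.all(feats.values == 0.0)

    def test_quadratic_homogeneity(self, speech2s, bank64, spec5ms):
        base = tk.extract_features(speech2s, bank64, spec5ms)
        scaled = tk.extract_features(speech2s.scaled(3.0), bank64, spec5ms)
        np.testing.assert_allclose(scaled.values, 9.0 * base.values, rtol=1e-9)

    def test_tone_lands_in_matching_channel(self, bank64, spec5ms):
        t = np.arange(16000) / RATE
        sig = tk.AudioSignal(np.sin(2 * np.pi * 1000.0 * t), RATE)
        feats = tk.extract_features(sig, bank64, spec5ms)
        channel = int(np.argmax(feats.values.mean(axis=0)))
        fc = bank64.center_freqs[channel]
        assert abs(erb_number(fc) - erb_number(1000.0)) < 1.0

    def test_rate_mismatch_rejected(self, bank64, spec5ms):
        sig = tk.AudioSignal(np.zeros(1600), 22050.0)
        with pytest.raises(ValueError):
            tk.extract_features(sig, bank64, spec5ms)

    def test_agrees_with_time_domain_filtering(self, bank64, spec5ms):
        """Spectral weighting must track a literal gammatone filter-and-frame
        oracle per frame (narrowband input at a channel center), up to one
        common calibration factor."""
        channel = 40
        fc = bank64.center_freqs[channel]
        t = np.arange(16000) / RATE
        env = 0.5 * (1 + np.sin(2 * np.pi * 3.0 * t))  # slow AM to vary frames
        sig = tk.AudioSignal(env * np.sin(2 * np.pi * fc * t), RATE)

        # oracle: filter with the 4th-order gammatone impulse response
        # (unit gain at fc), then sum squared Hann-windowed samples per frame
        b = 1.019 * tk.erb_bandwidth(fc)
        dur = int(0.05 * RATE)
        tt = np.arange(dur) / RATE
        g = tt**3 * np.exp(-2 * np.pi * b * tt) * np.cos(2 * np.pi * fc * tt)
        g /= np.abs(np.sum(g * np.exp(-2j * np.pi * fc * tt)))
        filtered = np.convolve(sig.samples, g)[: len(sig)]
        delay = int(np.argmax(np.abs(np.convolve(np.r_[1.0, np.zeros(dur)], g))))
        aligned = np.r_[filtered[delay:], np.zeros(delay)]
        frames = tk.frame_signal(tk.AudioSignal(aligned, RATE), spec5ms)
        oracle = np.sum(frames**2, axis=1)

        feats = tk.extract_features(sig, bank64, spec5ms).values[:, channel]
        keep = oracle > oracle.max() * 0.05  # avoid near-silent frames
        keep[:2] = keep[-2:] = False  # filter warm-up / tail edge frames
        ratio = feats[keep] / oracle[keep]
        np.testing.assert_allclose(ratio, np.median(ratio), rtol=0.15)


class TestComputeIrm:
    def test_unit_cases(self, bank64):
        times = np.zeros(1)
        s = tk.FeatureMatrix(np.full((1, 64), 2.0), times, bank64)
        v = tk.FeatureMatrix(np.full((1, 64), 2.0), times, bank64)
        assert np.all(tk.compute_irm(s, v).values == 0.5)

        v0 = tk.FeatureMatrix(np.zeros((1, 64)), times, bank64)
        assert np.all(tk.compute_irm(s, v0).values == 1.0)

        s1 = tk.FeatureMatrix(np.full((1, 64), 1.0), times, bank64)
        v4 = tk.FeatureMatrix(np.full((1, 64), 4.0), times, bank64)
        np.testing.assert_allclose(tk.compute_irm(s1, v4).values, 0.2)

    def test_silence_convention(self, bank64):
        times = np.zeros(1)
        zero = tk.FeatureMatrix(np.zeros((1, 64)), times, bank64)
        assert np.all(tk.compute_irm(zero, zero).values == 1.0)

    def test_shape_mismatch_rejected(self, bank64):
        s = tk.FeatureMatrix(np.ones((2, 64)), np.zeros(2), bank64)
        v = tk.FeatureMatrix(np.ones((3, 64)), np.zeros(3), bank64)
        with pytest.raises(ValueError):
            tk.compute_irm(s, v)

    @given(
        s2=st.floats(0.0, 1e6, allow_nan=False),
        v2_lo=st.floats(0.0, 1e6, allow_nan=False),
        v2_hi=st.floats(0.0, 1e6, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_transient_energy(self, bank64, s2, v2_lo, v2_hi):
        """Raising V^2 at fixed S^2 never raises the mask; entries stay in [0,1]."""
        v_lo, v_hi = sorted([v2_lo, v2_hi])
        times = np.zeros(1)
        s = tk.FeatureMatrix(np.full((1, 64), s2), times, bank64)
        m_lo = tk.compute_irm(s, tk.FeatureMatrix(np.full((1, 64), v_lo), times, bank64))
        m_hi = tk.compute_irm(s, tk.FeatureMatrix(np.full((1, 64), v_hi), times, bank64))
        assert np.all(m_hi.values <= m_lo.values + 1e-12)
        assert np.all((0 <= m_lo.values) & (m_lo.values <= 1))


class TestApplyMask:
    def test_identity_mask(self, mixture_m15, bank64, spec5ms):
        noisy = mixture_m15.mixture
        feats = tk.extract_features(noisy, bank64, spec5ms)
        out = tk.apply_mask(noisy, tk.Mask(np.ones(feats.values.shape)), bank64, spec5ms)
        sl = slice(160, len(noisy) - 160)
        err = tk.rms(out.samples[sl] - noisy.samples[sl]) / tk.rms(noisy.samples[sl])
        assert 20 * np.log10(err) <= -40.0

    def test_zero_mask_silences(self, mixture_m15, bank64, spec5ms):
        noisy = mixture_m15.mixture
        feats = tk.extract_features(noisy, bank64, spec5ms)
        out = tk.apply_mask(noisy, tk.Mask(np.zeros(feats.values.shape)), bank64, spec5ms)
        assert 20 * np.log10(tk.rms(out) / tk.rms(noisy) + 1e-20) <= -60.0

    def test_energy_non_expansion(self, mixture_m15, bank64, spec5ms):
        noisy = mixture_m15.mixture
        rng = np.random.default_rng(5)
        feats = tk.extract_features(noisy, bank64, spec5ms)
        mask = tk.Mask(rng.uniform(0, 1, size=feats.values.shape))
        out = tk.apply_mask(noisy, mask, bank64, spec5ms)
        in_frames = tk.frame_signal(noisy, spec5ms)
        out_frames = tk.frame_signal(out, spec5ms)
        in_e = np.sum(in_frames**2, axis=1)
        out_e = np.sum(out_frames**2, axis=1)
        # interior frames only: edge frames are touched by envelope compensation
        sl = slice(4, len(in_e) - 4)
        assert np.all(out_e[sl] <= in_e[sl] * (1 + 1e-6) + 1e-12)

    def test_frame_count_mismatch_rejected(self, mixture_m15, bank64, spec5ms):
        with pytest.raises(ValueError):
            tk.apply_mask(mixture_m15.mixture, tk.Mask(np.ones((3, 64))), bank64, spec5ms)

    def test_mask_bounds_enforced(self):
        with pytest.raises(ValueError):
            tk.Mask(np.array([[0.5, 1.2]]))
        with pytest.raises(ValueError):
            tk.Mask(np.array([[-0.1, 0.5]]))
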