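"""Gammatone-weighted time-frequency analysis, the ideal ratio mask, and
mask-based resynthesis.

The front end frames the waveform (5-ms Hann windows, 50% overlap at 16 kHz
by default), takes a zero-padded FFT, and collapses the power spectrum onto
a bank of 4th-order gammatone magnitude responses whose centers are equally
spaced on the ERB_N-number (Cam) scale.  Channel energies are the squared
magnitudes ``S_ij^2``; the ideal ratio mask for a clean/transient pair is

    IRM_ij = S_ij^2 / (S_ij^2 + V_ij^2)

per time frame j and channel i, a soft gain in [0, 1] that equals 1 where
the speech dominates and 0 where the transient dominates.  Applying a mask
maps the 64 channel gains back to FFT bins by a weight-normalized average,
scales each bin with phase preserved, and reconstructs by overlap-add.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import AudioSignal, FrameSpec, frame_signal, overlap_add

__all__ = [
    "erb_number",
    "erb_number_to_hz",
    "erb_bandwidth",
    "GammatoneBank",
    "build_bank",
    "FeatureMatrix",
    "Mask",
    "extract_features",
    "compute_irm",
    "apply_mask",
]

_SILENCE_FLOOR = 1e-12


def erb_number(freq_hz):
    """ERB_N-number (Cam) of a frequency: 21.4*log10(4.37*f/1000 + 1)."""
    return 21.4 * np.log10(4.37 * np.asarray(freq_hz, dtype=np.float64) / 1000.0 + 1.0)


def erb_number_to_hz(cams):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(cams, dtype=np.float64) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_bandwidth(freq_hz):
    """Equivalent rectangular bandwidth ERB_N(f) = 24.673*(4.368*f/1000 + 1) Hz."""
    return 24.673 * (4.368 * np.asarray(freq_hz, dtype=np.float64) / 1000.0 + 1.0)


@dataclass(frozen=True)
class GammatoneBank:
    """Spectral-weighting gammatone filterbank.

    ``bin_weights[i, k]`` is the squared magnitude response of channel ``i``
    at FFT bin ``k`` (rfft grid of ``fft_size`` at ``rate``).
    """

    center_freqs: np.ndarray
    bin_weights: np.ndarray
    rate: float
    fft_size: int

    def __post_init__(self) -> None:
        centers = np.asarray(self.center_freqs, dtype=np.float64)
        weights = np.asarray(self.bin_weights, dtype=np.float64)
        if centers.ndim != 1 or weights.ndim != 2:
            raise ValueError("centers must be 1-D and weights 2-D")
        if weights.shape[0] != centers.size:
            raise ValueError("one weight row per channel required")
        if centers.size > 1 and np.any(np.diff(centers) <= 0):
            raise ValueError("center frequencies must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("bin weights must be non-negative")
        object.__setattr__(self, "center_freqs", centers)
        object.__setattr__(self, "bin_weights", weights)

    @property
    def n_channels(self) -> int:
        return self.center_freqs.size


def build_bank(
    n_channels: int = 64,
    f_lo: float = 50.0,
    f_hi: float = 8000.0,
    rate: float = 16000.0,
    fft_size: int = 128,
) -> GammatoneBank:
    """Gammatone bank with centers equally spaced in Cams from f_lo to f_hi.

    Channel weights are squared 4th-order gammatone magnitude responses,
    ``|H(f)|^2 = [1 + ((f - fc)/b)^2]^-4`` with ``b = 1.019*ERB_N(fc)``,
    evaluated on the rfft bin grid.  With one channel the center sits at
    ``f_lo`` (degenerate-bank convention).
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("require 0 < f_lo < f_hi")
    if f_hi > rate / 2:
        raise ValueError("f_hi exceeds the Nyquist frequency")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if n_channels == 1:
        centers = np.array([f_lo])
    else:
        cams = np.linspace(erb_number(f_lo), erb_number(f_hi), n_channels)
        centers = erb_number_to_hz(cams)
        centers[0], centers[-1] = f_lo, f_hi  # pin the stated endpoints
    bin_freqs = np.fft.rfftfreq(fft_size, d=1.0 / rate)
    b = 1.019 * erb_bandwidth(centers)
    ratio = (bin_freqs[None, :] - centers[:, None]) / b[:, None]
    weights = (1.0 + ratio**2) ** -4
    return GammatoneBank(centers, weights, rate, fft_size)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-frame, per-channel gammatone energies (frame j rows, channel i cols)."""

    values: np.ndarray
    frame_times: np.ndarray
    bank: GammatoneBank

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        times = np.asarray(self.frame_times, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("feature values must be 2-D (frame x channel)")
        if np.any(values < 0):
            raise ValueError("energies must be non-negative")
        if times.shape != (values.shape[0],):
            raise ValueError("one frame time per frame required")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Mask:
    """Per-frame, per-channel gains in [0, 1] (true or estimated IRM)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("mask must be 2-D (frame x channel)")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("mask entries must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    @property
    def shape(self):
        return self.values.shape


def extract_features(signal: AudioSignal, bank: GammatoneBank, spec: FrameSpec) -> FeatureMatrix:
    """Frame, FFT and collapse the power spectrum onto the gammatone bank.

    ``value[j, i] = sum_k |X_jk|^2 * w_ik`` over rfft bins k.
    """
    if signal.rate != bank.rate:
        raise ValueError("signal rate does not match the bank rate")
    frames = frame_signal(signal, spec)
    spectra = np.fft.rfft(frames, n=bank.fft_size, axis=1)
    power = np.abs(spectra) ** 2
    values = power @ bank.bin_weights.T
    n = frames.shape[0]
    times = (np.arange(n) * spec.hop + spec.frame_len / 2.0) / spec.rate
    return FeatureMatrix(values, times, bank)


def compute_irm(clean_feats: FeatureMatrix, transient_feats: FeatureMatrix) -> Mask:
    """Ideal ratio mask S^2/(S^2 + V^2) from clean/transient feature pairs.

    Where both energies vanish (below 1e-12) the mask is defined as 1:
    silence carries no transient, so nothing should be attenuated.
    """
    s2 = clean_feats.values
    v2 = transient_feats.values
    if s2.shape != v2.shape:
        raise ValueError("clean and transient features must have identical shapes")
    denom = s2 + v2
    with np.errstate(invalid="ignore", divide="ignore"):
        irm = np.where(denom < _SILENCE_FLOOR, 1.0, s2 / np.maximum(denom, _SILENCE_FLOOR))
    return Mask(np.clip(irm, 0.0, 1.0))


def apply_mask(noisy: AudioSignal, mask: Mask, bank: GammatoneBank, spec: FrameSpec) -> AudioSignal:
    """Attenuate each TF unit of ``noisy`` by its mask gain and resynthesize.

    Channel gains are mapped to FFT-bin gains by the weight-normalized
    average ``g_k = sum_i m_i w_ik / sum_i w_ik`` (unity gain under an
    all-ones mask), applied to the complex spectrum (phase preserved), and
    the modified frames are overlap-added back to a waveform of the input
    length.
    """
    frames = frame_signal(noisy, spec)
    if mask.values.shape[0] != frames.shape[0]:
        raise ValueError("mask frame count does not match the framing of the signal")
    if mask.values.shape[1] != bank.n_channels:
        raise ValueError("mask channel count does not match the bank")
    spectra = np.fft.rfft(frames, n=bank.fft_size, axis=1)
    w = bank.bin_weights
    denom = np.maximum(w.sum(axis=0), _SILENCE_FLOOR)
    bin_gains = (mask.values @ w) / denom[None, :]
    spectra *= bin_gains
    modified = np.fft.irfft(spectra, n=bank.fft_size, axis=1)[:, : spec.frame_len]
    return overlap_add(modified, spec, length_hint=len(noisy))
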