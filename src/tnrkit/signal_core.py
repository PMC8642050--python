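"""Waveform primitives shared by every processing chain.

Audio is represented as a plain sampled waveform (:class:`AudioSignal`) on a
dimensionless full-scale ±1.0 axis.  Digital level is tied to acoustic level
by a single package-wide convention: an RMS of 1.0 (0 dBFS) corresponds to
``FULL_SCALE_DB_SPL`` dB SPL.  The default, 100 dB SPL, keeps 60-dB-SPL
speech (RMS 0.01) comfortably inside full scale with headroom for intense
transients.

Short-time processing uses an analysis window applied at framing time and the
same window again at synthesis; overlap-add divides by the summed
analysis-by-synthesis window envelope (floored at 1e-8), which reconstructs
unmodified frames exactly wherever the envelope is well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "FULL_SCALE_DB_SPL",
    "AudioSignal",
    "FrameSpec",
    "GainTable",
    "resample",
    "frame_signal",
    "overlap_add",
    "rms",
    "set_level",
    "apply_gain_filter",
    "algorithmic_latency",
    "read_wav",
    "write_wav",
]

#: SPL assigned to a full-scale (0 dBFS) RMS digital signal.
FULL_SCALE_DB_SPL = 100.0

_ENVELOPE_FLOOR = 1e-8


@dataclass(frozen=True)
class AudioSignal:
    """A finite mono waveform with its sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")
        if samples.size < 1:
            raise ValueError("AudioSignal needs at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    def scaled(self, factor: float) -> "AudioSignal":
        return replace(self, samples=self.samples * float(factor))


@dataclass(frozen=True)
class FrameSpec:
    """Framing grid for short-time analysis/synthesis.

    Parameters are in samples; :meth:`from_ms` converts from milliseconds.
    ``tukey_taper`` is the tapered fraction of a Tukey window and is ignored
    for the other window kinds.
    """

    frame_len: int
    hop: int
    rate: float
    window_kind: str = "hann"
    tukey_taper: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_len):
            raise ValueError("require 0 < hop <= frame_len")
        if self.window_kind not in ("hann", "tukey", "rect"):
            raise ValueError(f"unknown window kind {self.window_kind!r}")
        if not (0.0 <= self.tukey_taper <= 1.0):
            raise ValueError("tukey_taper must lie in [0, 1]")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @classmethod
    def from_ms(
        cls,
        frame_ms: float,
        hop_ms: float,
        rate: float,
        window_kind: str = "hann",
        tukey_taper: float = 0.5,
    ) -> "FrameSpec":
        return cls(
            frame_len=int(round(frame_ms * rate / 1000.0)),
            hop=int(round(hop_ms * rate / 1000.0)),
            rate=rate,
            window_kind=window_kind,
            tukey_taper=tukey_taper,
        )

    def window(self) -> np.ndarray:
        # periodic windows: correct for overlapped short-time analysis
        if self.window_kind == "hann":
            return sps.windows.hann(self.frame_len, sym=False)
        if self.window_kind == "tukey":
            return sps.windows.tukey(self.frame_len, alpha=self.tukey_taper, sym=False)
        return np.ones(self.frame_len)

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.frame_len:
            raise ValueError("signal shorter than one frame")
        return 1 + (n_samples - self.frame_len) // self.hop


@dataclass(frozen=True)
class GainTable:
    """Frequency-dependent linear amplification prescription (dB vs Hz)."""

    frequencies: np.ndarray
    gains_db: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=np.float64)
        gains = np.asarray(self.gains_db, dtype=np.float64)
        if freqs.ndim != 1 or freqs.shape != gains.shape:
            raise ValueError("frequencies and gains must be 1-D and equal length")
        if freqs.size < 1:
            raise ValueError("empty gain table")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "gains_db", gains)

    def gain_db_at(self, freqs: np.ndarray) -> np.ndarray:
        """Linear interpolation in dB; constant extrapolation at the edges."""
        return np.interp(freqs, self.frequencies, self.gains_db)


def resample(signal: AudioSignal, target_rate: float) -> AudioSignal:
    """Polyphase rational resampling with the resampler's anti-alias filter."""
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if target_rate == signal.rate:
        return signal
    ratio = Fraction(float(target_rate) / signal.rate).limit_denominator(10_000)
    out = sps.resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(out, target_rate)


def frame_signal(signal: AudioSignal, spec: FrameSpec) -> np.ndarray:
    """Slice into overlapping windowed frames, one per row.

    Frame count is ``1 + floor((N - frame_len) / hop)``; trailing samples that
    do not fill a frame are dropped (callers that need them pad first).
    """
    x = signal.samples
    n = spec.n_frames(x.size)
    idx = np.arange(spec.frame_len)[None, :] + spec.hop * np.arange(n)[:, None]
    return x[idx] * spec.window()[None, :]


def overlap_add(frames: np.ndarray, spec: FrameSpec, length_hint: int | None = None) -> AudioSignal:
    """Weighted overlap-add resynthesis of (possibly modified) frames.

    A synthesis window equal to the analysis window is applied and the result
    is divided by the accumulated analysis*synthesis envelope, so an
    unmodified analysis->synthesis round trip is exact wherever the envelope
    exceeds the 1e-8 floor (i.e. everywhere except a few edge samples for
    tapered windows).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 2 or frames.shape[1] != spec.frame_len:
        raise ValueError("frames are incompatible with the FrameSpec")
    n_frames = frames.shape[0]
    total = spec.frame_len + spec.hop * (n_frames - 1)
    if length_hint is None:
        length_hint = total
    win = spec.window()
    out = np.zeros(total)
    env = np.zeros(total)
    wsq = win * win
    for j in range(n_frames):
        sl = slice(j * spec.hop, j * spec.hop + spec.frame_len)
        out[sl] += frames[j] * win
        env[sl] += wsq
    out /= np.maximum(env, _ENVELOPE_FLOOR)
    if length_hint <= total:
        out = out[:length_hint]
    else:
        out = np.pad(out, (0, length_hint - total))
    return AudioSignal(out, spec.rate)


def rms(x: AudioSignal | np.ndarray) -> float:
    """Root-mean-square amplitude of a waveform or segment."""
    samples = x.samples if isinstance(x, AudioSignal) else np.asarray(x, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("rms of an empty segment is undefined")
    return float(np.sqrt(np.mean(samples**2)))


def set_level(
    signal: AudioSignal,
    target_db_spl: float,
    full_scale_db_spl: float = FULL_SCALE_DB_SPL,
) -> AudioSignal:
    """Scale so the RMS corresponds to ``target_db_spl`` under the package
    SPL convention (0 dBFS RMS == ``full_scale_db_spl`` dB SPL)."""
    current = rms(signal)
    if current <= 0:
        raise ValueError("cannot set the level of a silent signal")
    target_rms = 10.0 ** ((target_db_spl - full_scale_db_spl) / 20.0)
    return signal.scaled(target_rms / current)


def apply_gain_filter(signal: AudioSignal, table: GainTable, n_taps: int = 513) -> AudioSignal:
    """Linear-phase FIR amplification matching a dB-vs-frequency table.

    Frequency-sampling design on a linear grid (fir2-style) with the table
    interpolated linearly in dB.  The output is delayed by ``(n_taps-1)/2``
    samples and has the same length as the input.
    """
    if n_taps % 2 == 0:
        raise ValueError("n_taps must be odd for a type-I linear-phase filter")
    nyq = signal.rate / 2.0
    grid = np.linspace(0.0, nyq, 512)
    mag = 10.0 ** (table.gain_db_at(grid) / 20.0)
    taps = sps.firwin2(n_taps, grid / nyq, mag)
    out = sps.lfilter(taps, [1.0], signal.samples)
    return AudioSignal(out, signal.rate)


def algorithmic_latency(spec: FrameSpec) -> float:
    """Input-to-output delay in ms of the analysis-synthesis chain.

    One frame must be buffered before it can be processed, and the final
    ``frame_len - hop`` samples of its output only finish accumulating one
    hop later, giving ``frame + (frame - hop)`` assuming instantaneous
    per-frame computation.  For 5-ms frames at 50% overlap this is 7.5 ms.
    """
    return (2 * spec.frame_len - spec.hop) / spec.rate * 1000.0


def read_wav(path) -> AudioSignal:
    """Read a mono WAV file (16-bit PCM or 32/64-bit float) to full scale."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return AudioSignal(samples, float(rate))


def write_wav(path, signal: AudioSignal, subtype: str = "float") -> None:
    """Write mono WAV; ``subtype`` is ``"float"`` (32-bit) or ``"pcm16"``."""
    if subtype == "float":
        wavfile.write(path, int(signal.rate), signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
        wavfile.write(path, int(signal.rate), np.round(clipped * 32768.0).astype(np.int16))
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
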