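import numpy as np
import pytest

import tnrkit as tk

RATE = 16000.0


@pytest.fixture(scope="session")
def rate():
    return RATE


@pytest.fixture(scope="session")
def spec5ms():
    """The analysis grid of the RNN chain: 5-ms Hann frames, 50% overlap."""
    return tk.FrameSpec.from_ms(5.0, 2.5, RATE)


@pytest.fixture(scope="session")
def bank64():
    return tk.build_bank()


@pytest.fixture(scope="session")
def speech2s():
    return tk.synth_speech(2.0, seed=31)


@pytest.fixture(scope="session")
def transient_default():
    return tk.synth_transient(tk.TransientParams(), seed=32)


@pytest.fixture(scope="session")
def mixture_m15(speech2s, transient_default):
    """A seeded mixture at STR -15 dB with its exact components."""
    spec = tk.MixtureSpec(speech2s, transient_default, -15.0, seed=33)
    return tk.mix_at_str(spec)


def interior_error_db(reference: np.ndarray, reconstructed: np.ndarray, trim: int) -> float:
    """Relative RMS error in dB over the interior of a reconstruction."""
    sl = slice(trim, reference.size - trim)
    num = np.sqrt(np.mean((reconstructed[sl] - reference[sl]) ** 2))
    den = np.sqrt(np.mean(reference[sl] ** 2))
    return 20.0 * np.log10(num / den) if den > 0 else -np.inf
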