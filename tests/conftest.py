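import numpy as np
import pytest

from artispace import compute_mps, compute_spectrogram, normalize_mps
from artispace.sms import ModulationSpectrum
from artispace.synth import AudioGenSpec, generate_audio


def make_mps(power, tm_freqs, sm_freqs, normalized=False, tm_max=100.0, sm_max=10.0):
    """Build a ModulationSpectrum around an arbitrary power grid for
    contour/band unit tests."""
    power = np.asarray(power, dtype=float)
    tm_freqs = np.asarray(tm_freqs, dtype=float)
    sm_freqs = np.asarray(sm_freqs, dtype=float)
    tm_step = float(tm_freqs[1] - tm_freqs[0]) if len(tm_freqs) > 1 else 1.0
    sm_step = float(sm_freqs[1] - sm_freqs[0]) if len(sm_freqs) > 1 else 1.0
    return ModulationSpectrum(
        power=power,
        tm_freqs=tm_freqs,
        sm_freqs=sm_freqs,
        tm_step=tm_step,
        sm_step=sm_step,
        tm_max=tm_max,
        sm_max=sm_max,
        n_segments=1,
        normalized=normalized,
    )


@pytest.fixture(scope="session")
def am8_signal():
    return generate_audio(AudioGenSpec(kind="am_noise", am_rate_hz=8.0, duration_s=4.0, seed=1))


@pytest.fixture(scope="session")
def am8_mps(am8_signal):
    return normalize_mps(compute_mps(compute_spectrogram(am8_signal)))


@pytest.fixture(scope="session")
def tone_signal():
    return generate_audio(AudioGenSpec(kind="tone", tone_hz=1000.0, duration_s=4.0))


@pytest.fixture(scope="session")
def tone_mps(tone_signal):
    return normalize_mps(compute_mps(compute_spectrogram(tone_signal)))
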