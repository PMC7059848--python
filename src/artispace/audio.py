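"""Audio loading and standardization.

Every recording entering the analysis is put on the same footing: mono,
22,050 Hz, amplitude normalized to -18 dBFS.  An optional energy gate can
drop long silent stretches; it is off by default so that pre-cleaned
recordings pass through untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import AudioIOError, DegenerateInputError

__all__ = [
    "AudioSignal",
    "PreprocessConfig",
    "load_audio",
    "write_wav",
    "resample",
    "normalize_amplitude",
    "trim_nonspeech",
    "articulation_time",
    "preprocess",
]


@dataclass(frozen=True)
class AudioSignal:
    """A mono waveform: float64 samples in [-1, 1] and a sample rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class PreprocessConfig:
    """Standardization parameters.

    target_db is dB re full scale and must be negative; the normalization
    convention (peak vs RMS) is configurable because "-18 dB" alone does
    not pin it down.
    """

    target_rate: int = 22050
    target_db: float = -18.0
    normalization_mode: str = "peak"
    trim_enabled: bool = False
    trim_threshold_db: float = -40.0
    trim_min_gap_s: float = 0.1
    trim_frame_s: float = field(default=0.02, repr=False)

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.target_db >= 0:
            raise ValueError("target_db is dBFS and must be negative")
        if self.trim_threshold_db >= 0:
            raise ValueError("trim_threshold_db must be negative (below active level)")
        if self.normalization_mode not in ("peak", "rms"):
            raise ValueError("normalization_mode must be 'peak' or 'rms'")


_INT_SCALES = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


def load_audio(path: str | Path, config: PreprocessConfig | None = None) -> AudioSignal:
    """Read a WAV file, average channels to mono, rescale to [-1, 1] and
    resample to the configured rate.

    Raises AudioIOError for unreadable files and DegenerateInputError for
    zero-length audio.
    """
    config = config or PreprocessConfig()
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise AudioIOError(f"audio file not found: {path}") from None
    except Exception as exc:  # corrupt header, truncated file, ...
        raise AudioIOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise DegenerateInputError(f"zero-length audio: {path}")
    data = np.asarray(data)
    if data.dtype in _INT_SCALES:
        x = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    sig = AudioSignal(np.clip(x, -1.0, 1.0), int(rate))
    if sig.rate != config.target_rate:
        sig = resample(sig, config.target_rate)
    return sig


def write_wav(path: str | Path, sig: AudioSignal) -> None:
    """Write a signal as PCM 16-bit mono WAV (the pipeline's input dialect)."""
    x = np.clip(sig.samples, -1.0, 1.0)
    pcm = np.round(x * (2.0**15 - 1)).astype(np.int16)
    wavfile.write(Path(path), sig.rate, pcm)


def resample(sig: AudioSignal, target_rate: int) -> AudioSignal:
    """Band-limited polyphase resampling (Kaiser-windowed)."""
    if target_rate == sig.rate:
        return sig
    frac = Fraction(target_rate, sig.rate)
    y = resample_poly(sig.samples, frac.numerator, frac.denominator, window=("kaiser", 8.0))
    return AudioSignal(np.clip(y, -1.0, 1.0), target_rate)


def normalize_amplitude(sig: AudioSignal, target_db: float = -18.0, mode: str = "peak") -> AudioSignal:
    """Apply a pure gain so the peak (or RMS) level equals ``target_db`` dBFS."""
    if mode not in ("peak", "rms"):
        raise ValueError("mode must be 'peak' or 'rms'")
    x = sig.samples
    level = np.max(np.abs(x)) if mode == "peak" else math.sqrt(float(np.mean(x * x)))
    if level == 0.0:
        raise DegenerateInputError("cannot normalize silence (all-zero signal)")
    gain = 10.0 ** (target_db / 20.0) / level
    return AudioSignal(x * gain, sig.rate)


def _frame_rms_db(x: np.ndarray, frame_len: int) -> np.ndarray:
    n_frames = math.ceil(len(x) / frame_len)
    db = np.empty(n_frames)
    for i in range(n_frames):
        frame = x[i * frame_len : (i + 1) * frame_len]
        rms = math.sqrt(float(np.mean(frame * frame)))
        db[i] = 20.0 * math.log10(rms) if rms > 0 else -np.inf
    return db


def trim_nonspeech(sig: AudioSignal, config: PreprocessConfig | None = None) -> AudioSignal:
    """Energy gate: remove runs of low-energy frames longer than
    ``trim_min_gap_s``.

    A frame is low-energy when its RMS falls more than |trim_threshold_db|
    below the loudest frame.  Short dips (pauses between words) are kept so
    that normal speech rhythm is untouched.  Retained samples are
    concatenated unchanged.
    """
    config = config or PreprocessConfig()
    x = sig.samples
    if len(x) == 0 or np.max(np.abs(x)) == 0.0:
        raise DegenerateInputError("signal contains no energy above the gate")
    frame_len = max(1, round(config.trim_frame_s * sig.rate))
    db = _frame_rms_db(x, frame_len)
    active_level = float(np.max(db))
    below = db < (active_level + config.trim_threshold_db)
    if bool(np.all(below)):
        raise DegenerateInputError("signal entirely below the trim threshold")
    min_gap_frames = max(1, math.ceil(config.trim_min_gap_s * sig.rate / frame_len))
    keep = np.ones(len(db), dtype=bool)
    i = 0
    while i < len(db):
        if below[i]:
            j = i
            while j < len(db) and below[j]:
                j += 1
            if j - i >= min_gap_frames:
                keep[i:j] = False
            i = j
        else:
            i += 1
    sample_keep = np.repeat(keep, frame_len)[: len(x)]
    return AudioSignal(x[sample_keep], sig.rate)


def articulation_time(sig: AudioSignal) -> float:
    """Duration in seconds of the (cleaned) recording; a model covariate."""
    return sig.duration


def preprocess(sig: AudioSignal, config: PreprocessConfig | None = None) -> AudioSignal:
    """Full standardization chain: resample -> (trim) -> normalize."""
    config = config or PreprocessConfig()
    if sig.rate != config.target_rate:
        sig = resample(sig, config.target_rate)
    if config.trim_enabled:
        sig = trim_nonspeech(sig, config)
    return normalize_amplitude(sig, config.target_db, config.normalization_mode)
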