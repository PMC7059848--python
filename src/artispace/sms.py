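"""Speech Modulation Spectrum (SMS).

The SMS is the 2-D Fourier decomposition of a (log-amplitude) spectrogram.
It expresses how the energy of a recording is distributed over joint
temporal modulations (omega_t, in Hz: how fast the spectral envelope
changes over time) and spectral modulations (omega_f, in cycles/kHz: how
densely it ripples across frequency).  In speech, 2-10 Hz temporal
modulations track syllabic rhythm, 10-40 Hz track formant transitions, and
40-100 Hz carry place-of-articulation cues.  Normalized to unit sum, the
SMS is a probability distribution over spectro-temporal modulations.

Pipeline: ``compute_spectrogram`` (Gaussian-window short-time transform,
dB magnitude with a clipping floor) -> ``compute_mps`` (per-segment
mean-subtracted 2-D FFT power, averaged over non-overlapping segments)
-> ``normalize_mps`` -> ``band_energy`` / contour statistics.

Two choices matter for invariance properties.  The spectrogram is in dB, so
an overall waveform gain becomes an additive constant; per-segment mean
subtraction then removes it exactly, making the normalized SMS (and every
pixel statistic on it) gain-invariant.  Segments are a fixed length, so the
modulation grid (pixel sizes and extent) depends only on analysis
parameters, never on recording duration — pixel counts are comparable
across recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.fft
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import gaussian

from .audio import AudioSignal
from .errors import BandRangeError, DegenerateInputError

__all__ = [
    "Spectrogram",
    "ModulationSpectrum",
    "SMSConfig",
    "BANDS",
    "compute_spectrogram",
    "compute_mps",
    "normalize_mps",
    "band_energy",
    "temporal_marginal",
]

#: Canonical temporal-modulation bands (Hz); intervals are (lo, hi] on
#: |omega_t| so that adjacent bands partition the axis exactly.
BANDS: dict[str, tuple[float, float]] = {
    "syllabic": (2.0, 10.0),
    "formant_transition": (10.0, 40.0),
    "place": (40.0, 100.0),
}


@dataclass
class SMSConfig:
    """Analysis parameters for the spectrogram and its 2-D decomposition.

    window_bandwidth is the Gaussian window's spectral standard deviation in
    Hz (50 Hz ~ temporal sigma of 3.2 ms), frame_step the spectrogram hop in
    seconds, floor_db the dynamic range kept below the spectrogram maximum,
    segment_s the 2-D FFT segment length (1 s gives a 1 Hz temporal-
    modulation step so the 1-100 Hz analysis range falls on whole pixels).
    """

    window_bandwidth: float = 50.0
    frame_step: float = 0.001
    floor_db: float = 80.0
    segment_s: float = 1.0
    tm_max: float = 100.0
    sm_max: float = 10.0
    nfft: int = 512


@dataclass(frozen=True)
class Spectrogram:
    """Log-amplitude (dB) short-time spectrum: rows = frames, cols = frequency bins."""

    values: np.ndarray  # (n_frames, n_freq), dB, floored
    frame_step: float  # s between frames
    freq_step: float  # Hz between bins
    window_bandwidth: float  # Hz (Gaussian spectral std dev)
    floor_db: float
    rate: int

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.freq_step


@dataclass(frozen=True)
class ModulationSpectrum:
    """Power over (spectral modulation, temporal modulation).

    ``power[i, j]`` is the power at spectral modulation ``sm_freqs[i]``
    (cycles/kHz, >= 0 on the folded grid) and temporal modulation
    ``tm_freqs[j]`` (Hz, spanning both signs; the two half-planes carry
    down- and up-sweeps).
    """

    power: np.ndarray
    tm_freqs: np.ndarray
    sm_freqs: np.ndarray
    tm_step: float
    sm_step: float
    tm_max: float
    sm_max: float
    n_segments: int
    normalized: bool


def compute_spectrogram(
    sig: AudioSignal,
    window_bandwidth: float = 50.0,
    frame_step: float = 0.001,
    floor_db: float = 80.0,
    nfft: int = 512,
) -> Spectrogram:
    """Gaussian-window short-time spectrum in dB.

    The window's spectral standard deviation is ``window_bandwidth`` Hz,
    i.e. its temporal standard deviation is rate/(2*pi*bw) samples.  Only
    fully supported frames are produced (no edge padding), so a stationary
    input yields a strictly time-invariant spectrogram.  Values more than
    ``floor_db`` below the grid maximum are clipped to that floor.
    """
    if window_bandwidth <= 0 or frame_step <= 0 or floor_db <= 0:
        raise ValueError("window_bandwidth, frame_step and floor_db must be positive")
    x = sig.samples
    sigma = sig.rate / (2.0 * np.pi * window_bandwidth)
    # +-5 sigma support: the truncation edge is ~1e-6 of the peak, so its
    # leakage sidelobes fall below the floor_db clip and a stationary input
    # yields a strictly time-invariant spectrogram
    m = int(round(10.0 * sigma))
    m += (m + 1) % 2  # odd length, symmetric window
    if len(x) < m:
        raise DegenerateInputError(
            f"signal of {len(x)} samples is shorter than one {m}-sample analysis window"
        )
    hop = max(1, round(frame_step * sig.rate))
    win = gaussian(m, sigma)
    frames = sliding_window_view(x, m)[::hop] * win
    nfft = max(nfft, scipy.fft.next_fast_len(m))
    mag = np.abs(np.fft.rfft(frames, nfft, axis=1))
    peak = mag.max()
    if peak == 0.0:
        raise DegenerateInputError("all-zero signal has no spectrogram")
    db = 20.0 * np.log10(np.maximum(mag, peak * 1e-300))
    db = np.maximum(db, db.max() - floor_db)
    return Spectrogram(
        values=db,
        frame_step=hop / sig.rate,
        freq_step=sig.rate / nfft,
        window_bandwidth=window_bandwidth,
        floor_db=floor_db,
        rate=sig.rate,
    )


def compute_mps(
    spec: Spectrogram,
    segment_s: float = 1.0,
    tm_max: float | None = 100.0,
    sm_max: float | None = 10.0,
    crop: bool = True,
) -> ModulationSpectrum:
    """2-D Fourier power of the spectrogram, averaged over segments.

    The spectrogram is cut into non-overlapping segments of ``segment_s``
    seconds (a trailing remainder is discarded); each segment has its grand
    mean (over all dB values) subtracted before the 2-D FFT.  Power is
    |F|^2 / n_pixels, so the total over the full (uncropped) grid equals the
    sum of squared mean-subtracted dB values — a Parseval identity used as a
    correctness oracle.

    With ``crop=True`` the grid is folded to spectral modulations >= 0 and
    cropped to |omega_t| <= tm_max, omega_f <= sm_max.  ``crop=False``
    returns the full two-sided grid (for diagnostics and the Parseval
    check).
    """
    dt = spec.frame_step
    n_frames, n_f = spec.values.shape
    n_t = int(round(segment_s / dt))
    if n_t < 2:
        raise ValueError("segment_s must span at least two frames")
    if n_frames < n_t:
        raise DegenerateInputError(
            f"spectrogram has {n_frames} frames; one segment needs {n_t}"
        )
    n_seg = n_frames // n_t
    acc = np.zeros((n_f, n_t))
    for k in range(n_seg):
        seg = spec.values[k * n_t : (k + 1) * n_t, :]
        seg = seg - seg.mean()
        f2 = np.fft.fft2(seg)
        power = (f2.real**2 + f2.imag**2) / seg.size
        acc += np.fft.fftshift(power).T  # -> (spectral mod, temporal mod)
    acc /= n_seg
    tm = np.fft.fftshift(np.fft.fftfreq(n_t, dt))
    sm = np.fft.fftshift(np.fft.fftfreq(n_f, spec.freq_step)) * 1000.0  # cycles/kHz
    tm_step = 1.0 / (n_t * dt)
    sm_step = 1000.0 / (n_f * spec.freq_step)
    if crop:
        if tm_max is None or sm_max is None:
            raise ValueError("tm_max and sm_max are required when cropping")
        tol_t, tol_s = tm_step * 1e-9, sm_step * 1e-9
        col = np.abs(tm) <= tm_max + tol_t
        row = (sm >= -tol_s) & (sm <= sm_max + tol_s)
        acc, tm, sm = acc[np.ix_(row, col)], tm[col], sm[row]
    else:
        tm_max = float(np.max(np.abs(tm)))
        sm_max = float(np.max(np.abs(sm)))
    return ModulationSpectrum(
        power=acc,
        tm_freqs=tm,
        sm_freqs=sm,
        tm_step=tm_step,
        sm_step=sm_step,
        tm_max=float(tm_max),
        sm_max=float(sm_max),
        n_segments=n_seg,
        normalized=False,
    )


def normalize_mps(mps: ModulationSpectrum) -> ModulationSpectrum:
    """Scale power to unit sum: the SMS as a probability distribution."""
    total = float(mps.power.sum())
    if total <= 0.0:
        raise DegenerateInputError("cannot normalize an all-zero modulation spectrum")
    return replace(mps, power=mps.power / total, normalized=True)


def band_energy(
    mps: ModulationSpectrum, band: str | tuple[float, float]
) -> float:
    """Fraction of normalized power with lo < |omega_t| <= hi.

    ``band`` is a name from :data:`BANDS` or a custom ``(lo, hi)`` pair in
    Hz.  Both temporal-modulation half-planes and all spectral modulations
    are summed.  Intervals are half-open (lo, hi] so adjacent bands tile the
    axis without double counting.
    """
    if not mps.normalized:
        raise ValueError("band_energy requires a normalized modulation spectrum")
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if not 0.0 <= lo < hi:
        raise BandRangeError(f"invalid band ({lo}, {hi})")
    if hi > mps.tm_max + mps.tm_step * 1e-9:
        raise BandRangeError(
            f"band ({lo}, {hi}) Hz exceeds the grid's temporal-modulation "
            f"bound of {mps.tm_max:.3f} Hz"
        )
    tol = mps.tm_step * 1e-9
    abs_tm = np.abs(mps.tm_freqs)
    cols = (abs_tm > lo + tol) & (abs_tm <= hi + tol)
    return float(mps.power[:, cols].sum())


def temporal_marginal(mps: ModulationSpectrum) -> np.ndarray:
    """Power summed over spectral modulations, one value per omega_t pixel."""
    return mps.power.sum(axis=0)
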