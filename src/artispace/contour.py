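"""Articulation space: the pixel area of the minimal energy contour.

The statistic is the number of modulation-spectrum pixels inside the
lowest power level whose super-level set captures a target fraction
(default 99%) of the energy between 1 and 100 Hz temporal modulation.  A
recording that samples many distinct spectro-temporal modulations spreads
its energy over many pixels and needs a large contour; a monotone
recording concentrates energy in few pixels.  The contour is computed by
greedy descending-power pixel inclusion, which makes the pixel count exact
and independent of any plotting library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioSignal, articulation_time
from .errors import BandRangeError
from .sms import ModulationSpectrum, compute_mps, compute_spectrogram, normalize_mps

__all__ = ["ContourResult", "ContourConfig", "energy_contour", "articulation_space_area"]

#: Pixels with power below this fraction of total grid power are treated as
#: numerically zero (floating-point residue of exactly stationary inputs).
ZERO_TOL = 1e-15


@dataclass
class ContourConfig:
    """Contour parameters: energy fraction (0.99 default; 0.999 is the other
    convention in circulation) and the |omega_t| range in Hz."""

    fraction: float = 0.99
    tm_lo: float = 1.0
    tm_hi: float = 100.0
    both_halves: bool = True
    denominator: str = "band"  # or "grid"


@dataclass(frozen=True)
class ContourResult:
    """Threshold level, pixel mask (aligned to the MPS grid), and area."""

    level: float
    mask: np.ndarray
    area_px: int
    fraction_target: float
    fraction_achieved: float
    tm_range: tuple[float, float]


def energy_contour(
    mps: ModulationSpectrum,
    fraction: float = 0.99,
    tm_range: tuple[float, float] = (1.0, 100.0),
    both_halves: bool = True,
    denominator: str = "band",
) -> ContourResult:
    """Smallest super-level set holding ``fraction`` of the band's energy.

    Pixels with ``tm_range[0] <= |omega_t| <= tm_range[1]`` (one half-plane
    only if ``both_halves`` is false) are sorted by power, descending, and
    included until the cumulative power reaches ``fraction`` times the
    reference energy; ties at the final level are all included.  The
    reference energy is the restricted band's own total (``denominator=
    "band"``, default) or the whole grid's (``"grid"``).

    A band containing no power above the numerical floor yields area 0 with
    fraction_achieved 0 (e.g. a stationary tone, whose energy sits entirely
    in the excluded omega_t = 0 column).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not mps.normalized:
        raise ValueError("energy_contour requires a normalized modulation spectrum")
    if denominator not in ("band", "grid"):
        raise ValueError("denominator must be 'band' or 'grid'")
    lo, hi = tm_range
    if hi > mps.tm_max + mps.tm_step * 1e-9 or lo < 0:
        raise BandRangeError(
            f"tm_range ({lo}, {hi}) Hz outside the grid bound [0, {mps.tm_max:.3f}] Hz"
        )
    tol = mps.tm_step * 1e-9
    tm = mps.tm_freqs if both_halves else np.maximum(mps.tm_freqs, 0.0)
    abs_tm = np.abs(mps.tm_freqs)
    cols = (abs_tm >= lo - tol) & (abs_tm <= hi + tol)
    if not both_halves:
        cols &= mps.tm_freqs >= 0
    if not cols.any():
        raise BandRangeError(f"no grid pixels with |omega_t| in [{lo}, {hi}] Hz")

    total_grid = float(mps.power.sum())
    band = np.zeros_like(mps.power)
    band[:, cols] = mps.power[:, cols]
    band[band <= ZERO_TOL * total_grid] = 0.0
    band_total = float(band.sum())
    if band_total == 0.0:
        return ContourResult(
            level=0.0,
            mask=np.zeros_like(mps.power, dtype=bool),
            area_px=0,
            fraction_target=fraction,
            fraction_achieved=0.0,
            tm_range=(lo, hi),
        )
    denom = band_total if denominator == "band" else total_grid

    vals = np.sort(band[band > 0.0])[::-1]
    csum = np.cumsum(vals)
    target = fraction * denom
    k = int(np.searchsorted(csum, target * (1.0 - 1e-12)))
    k = min(k, len(vals) - 1)
    level = float(vals[k])
    mask = band >= level
    return ContourResult(
        level=level,
        mask=mask,
        area_px=int(mask.sum()),
        fraction_target=fraction,
        fraction_achieved=float(mps.power[mask].sum()) / denom,
        tm_range=(lo, hi),
    )


def articulation_space_area(sig: AudioSignal, config=None) -> tuple[int, dict]:
    """Full chain from a standardized waveform to the articulation-space
    area in pixels, plus a diagnostics record.

    ``config`` is an :class:`artispace.config.AnalysisConfig` (defaults are
    used when omitted).  Diagnostics include articulation time, the number
    of averaged segments, the realized energy fraction, grid steps, and an
    echo of the configuration.
    """
    from .config import AnalysisConfig  # local import to avoid a cycle

    config = config or AnalysisConfig()
    sms_cfg, ct_cfg = config.sms, config.contour
    spec = compute_spectrogram(
        sig,
        window_bandwidth=sms_cfg.window_bandwidth,
        frame_step=sms_cfg.frame_step,
        floor_db=sms_cfg.floor_db,
        nfft=sms_cfg.nfft,
    )
    mps = normalize_mps(
        compute_mps(spec, segment_s=sms_cfg.segment_s, tm_max=sms_cfg.tm_max, sm_max=sms_cfg.sm_max)
    )
    contour = energy_contour(
        mps,
        fraction=ct_cfg.fraction,
        tm_range=(ct_cfg.tm_lo, ct_cfg.tm_hi),
        both_halves=ct_cfg.both_halves,
        denominator=ct_cfg.denominator,
    )
    diagnostics = {
        "articulation_time_s": articulation_time(sig),
        "n_segments": mps.n_segments,
        "fraction_target": contour.fraction_target,
        "fraction_achieved": contour.fraction_achieved,
        "level": contour.level,
        "tm_step_hz": mps.tm_step,
        "sm_step_cyc_per_khz": mps.sm_step,
        "tm_lo": ct_cfg.tm_lo,
        "tm_hi": ct_cfg.tm_hi,
        "config": config.to_dict(),
    }
    return contour.area_px, diagnostics
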