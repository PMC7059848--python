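"""Plotting conveniences: contour overlay on the SMS and scatter-with-fit."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .contour import ContourResult
from .hlm import HLMResult
from .sms import ModulationSpectrum

__all__ = ["plot_mps_contour", "plot_scatter_fit"]


def plot_mps_contour(
    mps: ModulationSpectrum, contour: ContourResult | None, path: str | Path
) -> None:
    """Render the normalized SMS in dB with the energy contour overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    power = np.where(mps.power > 0, mps.power, np.nan)
    db = 10.0 * np.log10(power / np.nanmax(power))
    extent = (
        mps.tm_freqs.min(),
        mps.tm_freqs.max(),
        mps.sm_freqs.min(),
        mps.sm_freqs.max(),
    )
    im = ax.imshow(db, origin="lower", aspect="auto", extent=extent, vmin=-60, cmap="inferno")
    if contour is not None:
        ax.contour(
            mps.tm_freqs,
            mps.sm_freqs,
            contour.mask.astype(float),
            levels=[0.5],
            colors="cyan",
            linewidths=0.8,
        )
    ax.set_xlabel("temporal modulation (Hz)")
    ax.set_ylabel("spectral modulation (cycles/kHz)")
    fig.colorbar(im, ax=ax, label="power (dB re max)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter_fit(
    records: pd.DataFrame, covariate: str, result: HLMResult, path: str | Path
) -> None:
    """Scatter of articulation space against one covariate with the
    model-implied slope through the grand mean."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sub = records.dropna(subset=[covariate, "area_px"])
    ax.scatter(sub[covariate], sub["area_px"], s=12, alpha=0.6)
    row = result.fixed_effects.set_index("name")
    slope = row.loc[covariate, "estimate"]
    intercept = row.loc["(Intercept)", "estimate"]
    center = result.fit_meta.get("covariate_centers", {}).get(covariate, 0.0)
    xs = np.linspace(sub[covariate].min(), sub[covariate].max(), 50)
    ax.plot(xs, intercept + slope * (xs - center), color="crimson")
    ax.set_xlabel(covariate.upper())
    ax.set_ylabel("articulation space (pixels)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
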