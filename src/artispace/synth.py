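"""Synthetic fixtures with known ground truth.

Two generators make every pipeline stage verifiable without recordings:

* ``generate_audio`` builds waveforms whose modulation content is known by
  construction — amplitude-modulated noise with a programmed envelope rate,
  pure tones (no temporal modulation at all), and a "speech-like" bundle of
  formant carriers with syllabic envelopes and formant drift whose
  spectro-temporal diversity is controlled by a single ``richness`` knob.
  The speech-like signal is a modulation synthesizer, not a voice: it
  emulates the statistical structure the articulation-space statistic
  responds to (how many distinct modulation rates and spectral ripples are
  sampled), not intelligible speech.

* ``generate_cohort`` draws dyadic cohorts — same-sex pairs within
  countries, pair-level random intercepts, known fixed effects — as the
  generative twin of the mixed model, so estimator recovery, CI coverage
  and type-I error can be measured against programmed truth.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .hlm import build_design

__all__ = ["AudioGenSpec", "CohortGenSpec", "generate_audio", "generate_cohort"]


@dataclass
class AudioGenSpec:
    """What waveform to synthesize.

    kind: "am_noise" (white noise with raised-cosine envelope at
    ``am_rate_hz``), "tone" (stationary sinusoid at ``tone_hz``), or
    "speech_like".  ``richness`` in [0, 1] scales the number of envelope
    rates, the formant-drift excursion and the aspiration-noise mix of the
    speech-like signal; at 0 the signal has a single 4 Hz envelope and
    static formants.
    """

    kind: str = "speech_like"
    duration_s: float = 4.0
    rate: int = 22050
    am_rate_hz: float = 8.0
    tone_hz: float = 1000.0
    richness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("am_noise", "tone", "speech_like"):
            raise ValueError(f"unknown audio kind: {self.kind!r}")
        if not 0.0 <= self.richness <= 1.0:
            raise ValueError("richness must be in [0, 1]")
        if self.duration_s <= 0 or self.rate <= 0:
            raise ValueError("duration_s and rate must be positive")


def _peak_normalize(x: np.ndarray, peak: float = 0.9) -> np.ndarray:
    m = np.max(np.abs(x))
    return x * (peak / m) if m > 0 else x


def _speech_like(spec: AudioGenSpec, rng: np.random.Generator) -> np.ndarray:
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    r = spec.richness
    formants = ((500.0, 1.0), (1500.0, 0.6), (2500.0, 0.4))
    n_rates = 1 + int(round(8 * r))
    x = np.zeros(n)
    first_env = None
    for f0, amp in formants:
        # formant drift: slow quasi-random frequency wander, excursion ~ richness
        drift = np.zeros(n)
        if r > 0:
            for _ in range(3):
                g = rng.uniform(0.2, 1.0)
                c = rng.uniform(0.0, 1.0)
                drift += c * np.sin(2 * np.pi * g * t + rng.uniform(0, 2 * np.pi))
            drift *= 0.12 * r * f0 / 3.0
        phase = 2 * np.pi * np.cumsum(f0 + drift) / spec.rate
        # envelope: additive mixture of raised cosines, so every sampled rate
        # contributes its own spectral line and rate diversity widens (never
        # sparsifies) the modulation support
        rates = [rng.uniform(2.5, 5.0)]
        if n_rates > 1:
            rates += list(np.exp(rng.uniform(np.log(2.0), np.log(10.0 + 90.0 * r), n_rates - 1)))
        mod = np.zeros(n)
        total_depth = 0.0
        for rate_hz in rates:
            depth = rng.uniform(0.5, 1.0)
            total_depth += depth
            mod += depth * np.cos(2 * np.pi * rate_hz * t + rng.uniform(0, 2 * np.pi))
        env = np.maximum(1.0 + mod / max(total_depth, 1.0), 0.0)
        if first_env is None:
            first_env = env
        x += amp * env * np.sin(phase)
    if r > 0:
        x += 0.4 * r * rng.standard_normal(n) * first_env
    return x


def generate_audio(spec: AudioGenSpec) -> AudioSignal:
    """Deterministic synthesis of the waveform described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    if spec.kind == "am_noise":
        env = (1.0 + np.cos(2 * np.pi * spec.am_rate_hz * t)) / 2.0
        x = rng.standard_normal(n) * env
    elif spec.kind == "tone":
        x = np.sin(2 * np.pi * spec.tone_hz * t)
    else:
        x = _speech_like(spec, rng)
    return AudioSignal(_peak_normalize(x), spec.rate)


#: pairs per (country, gender) cell matching the study design:
#: India 9 male / 13 female, Italy 10/10, UK 18/25 pairs (85 pairs, 170 speakers).
STUDY_PAIRS: dict[str, tuple[int, int]] = {
    "India": (9, 13),
    "Italy": (10, 10),
    "UK": (18, 25),
}

#: generating fixed effects (simple coding, centered covariates), in pixels
DEFAULT_BETAS: dict[str, float] = {
    "intercept": 255.655,
    "gender": 51.015,  # male - female
    "country_india": -47.394,  # India - Italy
    "country_uk": 13.184,  # UK - Italy
    "age": 2.507,
    "duration": -0.168,
    "cr": 5.603,
    "aq": -1.834,
}


@dataclass
class CohortGenSpec:
    """A dyadic cohort: pairs per country x gender cell, generating fixed
    effects on the simple-coded design, and the two variance components.

    Covariates: closeness rating (integers 0-10), AQ (integers 5-40), age
    (integers 18-33), speaking duration (seconds, normal around 150 s —
    the nominal two-and-a-half-minute monologue — clipped to [60, 240]).
    ``cr_aq_corr`` induces a Gaussian-copula correlation between CR and AQ
    for robustness checks; ``n_missing_aq_pairs`` blanks AQ for that many
    whole pairs.
    """

    n_pairs: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(STUDY_PAIRS))
    betas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    sd_pair: float = 30.0
    sd_resid: float = 50.0
    cr_range: tuple[int, int] = (0, 10)
    aq_range: tuple[int, int] = (5, 40)
    age_range: tuple[int, int] = (18, 33)
    duration_mean_s: float = 150.0
    duration_sd_s: float = 25.0
    cr_aq_corr: float = 0.0
    n_missing_aq_pairs: int = 0
    seed: int = 0


def _correlated_integers(
    rng: np.random.Generator, n: int, lo1: int, hi1: int, lo2: int, hi2: int, corr: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-uniform marginals with a Gaussian-copula correlation."""
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    from scipy.stats import norm

    u = norm.cdf(z)
    a = np.floor(u[:, 0] * (hi1 - lo1 + 1)).clip(0, hi1 - lo1).astype(int) + lo1
    b = np.floor(u[:, 1] * (hi2 - lo2 + 1)).clip(0, hi2 - lo2).astype(int) + lo2
    return a, b


def generate_cohort(spec: CohortGenSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort and return (records, truth).

    The outcome is built on exactly the coding the fitter uses by default
    (simple contrasts, covariates centered at the realized sample means),
    so the programmed betas are directly recoverable.  ``truth`` echoes the
    betas, variance components and coding.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pair_idx = 0
    for country, (male_pairs, female_pairs) in spec.n_pairs.items():
        for gender, n_pairs in (("male", male_pairs), ("female", female_pairs)):
            for _ in range(n_pairs):
                pair_id = f"pair{pair_idx:03d}"
                for member in (1, 2):
                    rows.append(
                        {
                            "participant_id": f"{pair_id}_p{member}",
                            "pair_id": pair_id,
                            "gender": gender,
                            "country": country,
                        }
                    )
                pair_idx += 1
    df = pd.DataFrame(rows)
    n = len(df)
    if spec.cr_aq_corr != 0.0:
        cr, aq = _correlated_integers(
            rng, n, *spec.cr_range, *spec.aq_range, spec.cr_aq_corr
        )
    else:
        cr = rng.integers(spec.cr_range[0], spec.cr_range[1] + 1, size=n)
        aq = rng.integers(spec.aq_range[0], spec.aq_range[1] + 1, size=n)
    df["age"] = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    df["duration"] = np.clip(
        rng.normal(spec.duration_mean_s, spec.duration_sd_s, size=n), 60.0, 240.0
    )
    df["cr"] = cr
    df["aq"] = aq.astype(float)

    beta_order = (
        "intercept",
        "gender",
        "country_india",
        "country_uk",
        "age",
        "duration",
        "cr",
        "aq",
    )
    beta = np.array([spec.betas[k] for k in beta_order])
    X, _, _ = build_design(df, coding="simple", center=True)
    pair_codes = pd.factorize(df["pair_id"])[0]
    b = rng.normal(0.0, spec.sd_pair, size=pair_codes.max() + 1)
    e = rng.normal(0.0, spec.sd_resid, size=n)
    df["area_px"] = X @ beta + b[pair_codes] + e

    if spec.n_missing_aq_pairs > 0:
        blank = rng.choice(df["pair_id"].unique(), size=spec.n_missing_aq_pairs, replace=False)
        df.loc[df["pair_id"].isin(blank), "aq"] = np.nan

    truth = {
        "betas": {k: spec.betas[k] for k in beta_order},
        "sd_pair": spec.sd_pair,
        "sd_resid": spec.sd_resid,
        "coding": "simple",
        "n_pairs": int(pair_idx),
        "n_obs": n,
    }
    return df, truth
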