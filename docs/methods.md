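# Methods

This package quantifies vocal modulation in speech recordings by the
*articulation space* — the pixel area of the energy contour of the speech
modulation spectrum — and relates it to dyad-level (interpersonal
closeness) and individual-level (autistic traits) predictors with a
mixed-effects model over speaker pairs. This note records the models, the
parameter choices that matter, and where the design was genuinely open.

## From waveform to modulation spectrum

Recordings are standardized to mono, 22,050 Hz, with amplitude normalized
to −18 dBFS. "−18 dB" alone does not fix a measurement convention, so both
peak (default) and RMS normalization are provided
(`PreprocessConfig.normalization_mode`); because the modulation spectrum is
computed from a log spectrogram with per-segment mean subtraction, the
analysis downstream is exactly gain-invariant and the choice does not
affect areas — it matters only if waveforms are exported. Multi-channel
input is averaged to one channel. Resampling is band-limited polyphase
(Kaiser window); gain error on a 1 kHz tone is well below 0.1 dB.

An optional energy gate (`trim_enabled`, default **off**) removes runs of
frames more than 40 dB (configurable) below the loudest frame lasting
longer than 0.1 s. It is a coarse automatic stand-in for careful manual
removal of non-speech sounds: it removes silence and low-level noise floors
but cannot distinguish laughter or coughs from speech. Pre-cleaned audio
should be run with the gate off, which reproduces input durations exactly.

The spectrogram uses a Gaussian window with spectral standard deviation 50
Hz (temporal σ = 1/(2π·50) ≈ 3.18 ms), hop 1 ms, magnitude in dB clipped 80
dB below the grid maximum. The window support is ±5σ: with shorter support
the truncation-edge sidelobes sit above the −80 dB floor and beat with the
frame phase, so even a stationary tone acquires spurious temporal
modulation. A 50 Hz bandwidth resolves temporal modulations well past the
100 Hz analysis bound (modulation Nyquist is 500 Hz at a 1 ms hop) while
keeping spectral modulations up to ~11 cycles/kHz on the grid.

The modulation spectrum is the squared-magnitude 2-D FFT of the dB
spectrogram, computed on non-overlapping 1 s segments (trailing remainder
discarded), each segment mean-subtracted, and averaged across segments.
Power is scaled as |F|²/n_pixels so the total over the uncropped grid
equals the summed squared mean-subtracted dB values — a Parseval identity
the tests verify to 1e−6. The grid is folded to spectral modulations ≥ 0
(the discarded half-plane is the point-symmetric mirror; up- and
down-sweeps remain separated by the sign of the temporal modulation) and
cropped to |ω_t| ≤ 100 Hz, ω_f ≤ 10 cycles/kHz. One-second segments put the
temporal-modulation pixel pitch at ~1 Hz, so the 1–100 Hz analysis range
falls on whole pixels. The grid shape depends only on analysis parameters,
never on recording length, so pixel counts are comparable across
recordings; the pipeline warns if recordings land on different grids.

Two consequences of the log-domain + mean-subtraction design are used as
test oracles: waveform gain and polarity changes leave the normalized
spectrum bit-comparable (areas exactly equal), and a stationary input
concentrates ≥99% of power in the ω_t = 0 column.

## Articulation space

After normalizing the modulation spectrum to unit sum, the articulation
space is the number of pixels in the smallest super-level set containing a
target fraction of the energy among pixels with 1 ≤ |ω_t| ≤ 100 Hz. It is
computed by sorting band pixels by power and including them greedily, with
ties at the final level all included — a definition that is exact in pixels
and independent of any contour-plotting routine, and is verified against
exhaustive threshold search on small grids. The band's own total is the
default denominator ("99% of the energy *from 1 to 100 Hz*"); the
whole-grid denominator is a config switch, as is counting a single
temporal-modulation half-plane.

The energy fraction defaults to 0.99; 0.999 is in circulation for the same
statistic and is available as `ContourConfig(fraction=0.999)`. Both
half-planes are counted by default. Pixels below 1e−15 of the total grid
power are treated as numerical zeros: a stationary tone's band energy is
pure floating-point residue, and without the floor its "99% contour" would
cover thousands of meaningless pixels; with it, degenerate inputs yield
area ≈ 0 (with `fraction_achieved` 0), which is the scientifically sensible
reading. Areas are meaningful only relative to a fixed grid and
configuration — the features table carries a config hash, and areas from
different hashes must not be compared.

## Cohort model

Each speaker contributes one area; speakers are nested in same-sex,
same-country pairs:

    area_ij = β₀ + β·x_ij + b_j + e_ij,  b_j ~ N(0, τ²), e_ij ~ N(0, σ²)

with fixed effects gender, country, age, speech duration, closeness rating
(CR, 0–10), and Autism Spectrum Quotient (AQ), fitted by REML
(statsmodels MixedLM). Satterthwaite degrees of freedom are computed
in-package from the REML information matrix of (τ², σ²); the whole
inference path (estimates, SEs, variance components, dfs) is cross-checked
in the test suite against R's lmerTest on identical data.

Contrast coding defaults to *simple* coding — male −.5/+.5, country
contrasts against Italy as indicator−1/3, covariates grand-mean centered —
so the intercept sits at the (unweighted) grand mean and each factor row
reads as a level difference ("2−1", "India−Italy", "UK−Italy"). Treatment
coding is available; the coding used is always printed in `fit_meta`,
because a fixed-effects table is uninterpretable without it. Rows with any
missing model variable are dropped listwise at fit time with the count
logged (AQ is the realistic missingness case). `ModelConfig(var_pair=0.0)`
profiles the random intercept out, under which the fit provably reduces to
OLS — used as a degenerate-case oracle.

### Calibration

A simulation study at the default cohort size (85 pairs, 170 speakers; τ =
30 px, σ = 50 px) shows: CR-slope estimates unbiased within Monte-Carlo
error; REML variance components near-unbiased (mean τ̂² ≈ 865 at τ² = 900
over 200 replicates); type-I error for the CR slope 0.058 at 500 null
replicates; and 95% CI coverage of ~0.93–0.95 across replicate batches.
Coverage of plug-in mixed-model intervals sits slightly below nominal at
this design size for within-pair covariates; a Kenward–Roger-type adjusted
covariance was evaluated and changed coverage by less than half a point
here, so the field-standard Satterthwaite inference (what lmerTest and
jamovi report) is kept. The practical reading: single-study CIs for a
within-pair covariate at n = 170 are mildly optimistic, a property of the
method, not of this implementation.

## Synthetic data

`generate_audio` produces three waveform families with known modulation
content: white noise with a raised-cosine envelope at a programmed rate
(`am_noise` — its modulation-spectrum peak location is an oracle), a
stationary tone (no temporal modulation — the degenerate oracle), and a
`speech_like` bundle: three formant-like carriers (500/1500/2500 Hz) with
slowly drifting frequencies, each amplitude-modulated by an *additive*
mixture of raised cosines whose number of rates, rate range (2 Hz up to
10–100 Hz), drift excursion, and aspiration-noise mix all scale with a
single `richness` knob in [0, 1]. An additive mixture is used deliberately:
a product of envelopes concentrates energy into rarer bursts as factors are
added, which *shrinks* the occupied modulation area — the opposite of what
a diversity knob must do. Median area is monotone in richness (checked at
0.2/0.5/0.8 over 10 seeds). The generator emulates the statistical
structure the area statistic responds to, not speech itself: no
glottal-source harmonic stack, no phonotactics, no pauses or turn-taking.
Passing tests therefore demonstrate correctness of the measurement chain
and ordering behaviour, not performance on real voices.

`generate_cohort` is the generative twin of the mixed model: pairs per
country×gender cell default to the study design (India 9/13, Italy 10/10,
UK 18/25 male/female pairs), fixed effects applied on exactly the coding
the fitter uses, pair intercepts and residuals Gaussian. Covariates are
integer CR 0–10, integer AQ 5–40, integer age 18–33, and duration normal
around 150 s (a ~2.5 min monologue) clipped to [60, 240] s, drawn
independently by default with an optional Gaussian-copula CR–AQ
correlation knob. Everything is bit-deterministic given the seed.

The `synth cohort` CLI writes speech-like WAVs whose richness increases
with the speaker's CR and varies nominal duration per speaker by a uniform
0.8–1.3 factor — without that variation the duration covariate is constant
and the demonstration model is singular.

## Numerical choices and limitations

- Segment remainder shorter than 1 s is discarded; recordings shorter than
  ~1.2 s (one segment plus window support) cannot be analyzed.
- Contour ties are resolved by including all pixels at the threshold
  level, so nested fractions give nested masks up to level ties.
- Band intervals are half-open (lo, hi] on |ω_t| so adjacent bands tile
  the axis; the contour band is closed on both ends.
- The features cache is keyed by (audio bytes, config hash); model-only
  reruns do not recompute spectra.
- Simulation sizes in the tests and acceptance script (200 recovery
  replicates, 500 null replicates, 4 s fixtures, 12-pair end-to-end
  cohorts) are chosen to make the Monte-Carlo error small relative to the
  tolerances being checked while keeping the default run quick on one CPU.
- The pipeline does not implement perceptual loudness normalization, noise
  reduction, diarization, or any speech/non-speech classification beyond
  the energy gate; recordings are assumed pre-cleaned.
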