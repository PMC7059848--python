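# artispace

Tools for quantifying **vocal modulation** in speech recordings and relating
it to dyad- and individual-level predictors.

Speakers differ in how richly they modulate their voice — how many distinct
spectro-temporal gestures (syllabic rhythm, formant transitions,
place-of-articulation cues) their speech samples. `artispace` measures this
with the **speech modulation spectrum** (SMS): the 2-D Fourier decomposition
of a log spectrogram, giving power as a joint distribution over temporal
modulation ω_t (Hz) and spectral modulation ω_f (cycles/kHz). The summary
statistic is the **articulation space**: the number of SMS pixels inside the
smallest power contour that captures 99% of the energy at temporal
modulations 1 ≤ |ω_t| ≤ 100 Hz. Rich, varied articulation spreads energy
over many modulations and yields a large area; monotone speech concentrates
it and yields a small one.

For cohorts of same-sex speaker pairs (each member rates closeness to the
other and completes the Autism Spectrum Quotient), the package fits the
hierarchical linear model

    area_ij = β₀ + β₁·gender + β₂..₃·country + β₄·age + β₅·duration
              + β₆·CR + β₇·AQ + b_j + e_ij,
    b_j ~ N(0, τ²) per pair, e_ij ~ N(0, σ²),

by REML, reporting fixed effects with 95% CIs and Satterthwaite approximate
degrees of freedom (cross-validated against R's `lmerTest`).

A synthetic-data module generates audio with *known* modulation content and
dyadic cohorts with *known* effects, so every stage of the pipeline is
testable without any recordings.

## Worked example

Synthesize a 12-pair cohort (speech-like audio whose modulation richness
increases with the speaker's closeness rating), then run the full pipeline:

```bash
artispace synth cohort --pairs "India=4,Italy=4,UK=4" --duration 3.0 --seed 7 --out cohort/
artispace all --manifest cohort/manifest.csv --out results/
cat results/model_report.txt
```

```
Hierarchical linear model: articulation space (pixels)
Method: REML  coding: simple  n_obs: 24  n_pairs: 12
Random-intercept variance (pair): 0.001   Residual variance: 84365.003

Name          Effect          Estimate       SE     Lower     Upper      df       t       p
(Intercept)   (Intercept)    17742.458   59.289 17595.682 17889.234     5.7 299.253  0.0000
gender        2-1             -102.892  139.767  -422.290   216.506     8.4  -0.736  0.4816
country_india India-Italy       -0.750  167.441  -380.981   379.481     8.8  -0.004  0.9965
country_uk    UK-Italy         -25.194  165.005  -406.635   356.247     7.9  -0.153  0.8825
age           Age                4.273   13.824   -25.041    33.587    15.9   0.309  0.7612
duration      Duration         520.733  162.402   175.961   865.506    15.7   3.206  0.0056
cr            CR               125.478   22.544    76.737   174.219    12.9   5.566  0.0001
aq            AQ                -3.393    7.126   -18.561    11.775    15.2  -0.476  0.6407
```

The generator tied modulation richness to CR, and the model recovers
exactly that: a strong positive CR effect (125.5 pixels per rating point,
p = 0.0001) and null effects for the covariates that played no role. Under
the default *simple* contrast coding the intercept is the grand mean area;
"2−1" is male minus female; country rows are differences from Italy.
`results/features.csv` holds one row per speaker (area in pixels,
articulation time, contour settings, config hash), and
`results/descriptives.csv` the country × gender N/mean/SD table.

A single recording:

```bash
artispace synth audio --kind speech_like --richness 0.7 --duration 4 --seed 3 --out rich.wav
artispace area --wav rich.wav
```

```json
{
  "area_px": 18450,
  "articulation_time_s": 4.0,
  "n_segments": 3,
  "fraction_achieved": 0.9900021939422736,
  ...
}
```

18,450 pixels of the ~22,000-pixel analysis band are needed to hold 99% of
this signal's modulation energy — a richly modulated signal. The same
command on `--richness 0.0` audio (single envelope rate, static formants)
gives areas around 1,000–2,600, and on a pure tone essentially zero, since
a stationary signal has no energy at |ω_t| ≥ 1 Hz at all.

The same analyses are available as a library:

```python
from artispace import (AudioGenSpec, generate_audio, articulation_space_area,
                       CohortGenSpec, generate_cohort, fit_hlm)

sig = generate_audio(AudioGenSpec(kind="speech_like", richness=0.7, seed=3))
area, diagnostics = articulation_space_area(sig)

records, truth = generate_cohort(CohortGenSpec(seed=0))  # 85 pairs, known betas
result = fit_hlm(records)
print(result.fixed_effects)
```

## Configuration

All analysis parameters live in one YAML config (`artispace all --config`):
spectrogram window bandwidth (50 Hz), frame step (1 ms), dB floor (80),
segment length (1 s), grid bounds (100 Hz, 10 cyc/kHz), contour fraction
(0.99; 0.999 optional), temporal-modulation range (1–100 Hz), normalization
mode (peak/RMS at −18 dBFS), optional silence gate, and model contrast
coding. A hash of the analysis-relevant configuration stamps every output;
areas computed under different hashes are not comparable. See
`docs/methods.md` for the rationale behind each default and the known
limitations.
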