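# Methods

This note records the signal-processing and statistical conventions the
package commits to, the reasoning behind choices that were genuinely
open, and what the synthetic benchmark does and does not demonstrate.

## Preprocessing

Events are cut from recordings by annotation, then conditioned in a
fixed order: band-pass filter at the native rate, resample to 8 kHz,
peak-scale into [−1, 1]. The band-pass is a single 5th-order
Butterworth design (a 10th-order transfer function), 150–2000 Hz,
realised in second-order sections and applied **causally** (single
pass). Zero-phase forward–backward filtering was deliberately not used:
a causal filter matches the streaming, wearable-device setting the
benchmark targets. The −3 dB points sit at the 150/2000 Hz corners by
the Butterworth definition; the 150 Hz high-pass edge is what suppresses
heart sounds and DC drift.

Amplitude scaling divides by the peak absolute value. A scaling that
maps into [−1, 1] cannot simultaneously preserve mean and variance
unless it is the identity; peak normalisation is the only [−1, 1]
mapping that preserves waveform shape and zero offset, so it is the
convention adopted. All-zero segments are rejected rather than passed
through silently.

Events shorter than 64 ms are rejected at construction: the framed
features (tonality, ASE flux, spectral entropy) need at least two 32 ms
analysis frames, and the LPC segmentation needs 51.2 ms.

## Spectral estimation

Two estimators back every spectral feature:

* **Whole-event modified periodogram** with a Kaiser window, shape
  parameter β = 38, spanning the full event. β = 38 gives extreme
  sidelobe suppression (> 280 dB), appropriate when a single narrowband
  wheeze component must not leak across the spectrum. The window
  *length* always equals the event length. Normalisation is fixed by
  Parseval: one-sided bin powers sum to Σ(x·w)²/Σw², i.e. the windowed
  mean-square power with window power normalisation (tested to 1e−6 on
  white noise).
* **Framed spectrogram**, 32 ms frames with 8 ms hop (256/64 samples at
  8 kHz), Hann window, last partial frame dropped, same per-frame
  normalisation. FFT length equals frame length (no zero padding).

## Feature conventions

Where the feature definitions admit dialects, the package fixes them as
follows:

* **Averaged PSD** — 32 contiguous equal-width bands over [0, 1950] Hz
  (width 60.9375 Hz), half-open `[lo, hi)` with the last band closed;
  linear (not log) mean bin power per band.
* **Wavelet** — 5-level db4 decomposition; per detail band D1..D5 the
  absolute mean, mean power and SD (15 features), plus adjacent-band
  absolute-mean ratios D1/D2 … D4/D5 and D5/A5 (5 features), closing
  the chain at the approximation band so the family totals 20.
* **MFCC** — one spectrum for the whole event; 26 triangular filters on
  the standard mel warp 2595·log10(1 + f/700) over 0–4000 Hz; log
  energies floored at 1e−12 of their maximum; orthonormal DCT-II;
  coefficients of order 0..12.
* **LPC** — 410-sample segments (51.2 ms) with 102-sample (12.8 ms)
  overlap; order-6 autocorrelation method via Levinson–Durbin with the
  analysis-filter sign convention A(z) = 1 + Σ aₖ z⁻ᵏ (so an AR(1)
  process with pole 0.9 yields a₁ ≈ −0.9). The family reports the six
  segment-averaged coefficients, the segment-averaged order-6 error
  power, and the segment-averaged E⁽⁰⁾/E⁽⁴⁾ ratio — ratio first, then
  average, consistent with the per-segment-then-combine pattern of the
  other framed features. Eight features total.
* **Percentile frequencies** — lowest bin frequency at which cumulative
  periodogram power reaches x% of the total ("≥" search, bin centre
  returned). f25/f50/f75 are also standalone features; f90 appears only
  in ratios.
* **Entropy** — per-frame Shannon entropy (bits) of the frame spectrum
  normalised to a probability vector; features are max−min, max/min and
  mean over frames. A frame entropy of exactly 0 (single-bin spectrum)
  would make the ratio undefined; it is reported as the sentinel 1e6
  with a logged warning. The Rényi entropy (α = 2, natural log) uses a
  100-bin amplitude histogram on [−1, 1]; the discretisation is a
  package choice since the amplitude distribution is continuous.
* **Power ratio** — max bin power in [250, 800] Hz over mean bin power
  in [60, 900] Hz, both closed intervals, from the whole-event
  periodogram.
* **ASE flux** — quarter-octave band edges 62.5·2^(j/4), j = 0..20
  (62.5–2000 Hz): 20 interior bands plus the below-62.5 Hz and
  above-2000 Hz remainders, 22 bands per frame, in dB with the 1e−12
  relative floor; the feature is the mean Euclidean norm of consecutive
  frame differences.
* **Tonality index** — per frame, spectral flatness in dB
  (10·log10 of geometric/arithmetic mean, floored bins) mapped by
  α = min(SFM_dB/−60, 1) clamped to [0, 1], then averaged over frames;
  1 is tonal, 0 noise-like.
* **Mean crossing irregularity** — coefficient of variation (population
  SD over mean) of the intervals between crossings of the signal's own
  mean; exact zeros attach to the preceding sign so a grazing touch
  does not double-count.
* **Misc spectral descriptors** (roll-offs, quartiles, centroid,
  spread, skewness, kurtosis, flatness, crest, slope, decrease,
  irregularity, brightness) are computed on the whole-event Kaiser
  periodogram. The brightness cutoff is 1500 Hz (common practice; the
  quantity is the fraction of power above the cutoff). Zero spectral
  spread degrades skewness/kurtosis to 0 with a warning. Time-domain
  descriptors (RMS, SD, ZCR) need no transform; band power is the
  periodogram power summed over the 150–2000 Hz pass band, which equals
  the mean-square power after preprocessing up to filter roll-off.

All logarithms use a floor of 1e−12 relative to the spectrum maximum.
Band-limited statistics use closed frequency intervals.

## Evaluation protocol

* **Scaling** (training min/max to [−1, 1]) is fitted on the training
  half only; test values may fall outside [−1, 1] and are not clipped.
  Features constant on the training half are excluded with a warning.
* **Splits** are patient-independent: recordings, not events, are
  partitioned 50/50, so no recording contributes to both halves.
* **Threshold candidates** are midpoints of consecutive sorted unique
  training values plus one sentinel below the minimum and one above the
  maximum. Sentinels are placed at min−1/max+1 (finite, scale-appropriate
  for features living in [−1, 1]) rather than ±∞ so selected rules
  always carry a finite threshold. An event equal to the threshold
  classifies negative.
* **Cross-validation**: candidates come from the pooled training sweep;
  the mean objective over stratified validation folds selects the rule.
  Ties break toward direction "greater", then toward the smaller
  threshold — a reproducible, data-independent convention. On small
  instances the selected rule provably equals the exhaustive argmax
  (tested against a loop-based oracle).
* **Logistic regression** uses a weak ridge penalty (λ = 1e−4 on the
  weights): the exhaustive subset search inevitably encounters linearly
  separable subsets where unpenalised ML diverges. Sequential forward
  selection optimises an internal cross-validated objective on the
  training half — never the test half, which would be leakage — and
  reports both curves.
* **Determinism**: a master seed drives split seeds (seed + repetition
  index) and fold shuffles; repeated runs are bit-identical.
* **Undefined metrics** (zero denominators) propagate as missing values
  rather than silent zeros, except MCC's standard 0 convention when a
  marginal sum vanishes.
* **AUC orientation**: curves are swept in the direction giving
  AUC ≥ 0.5 and the direction is recorded, so the implied threshold
  rule is recoverable. The trapezoidal area equals the Mann–Whitney
  U/(n₁n₂) with ties half-counted (tested to 1e−12).
* **Rank-sum test**: exact enumeration for pooled n ≤ 12 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction. The common-language effect size is the fraction of
  (wheeze, normal) pairs where the wheeze value is larger, ties half.
* **DBM/OVS** reads box-plot geometry from the data: quartiles by
  linear interpolation, Tukey whiskers at the furthest point within
  1.5 IQR; the ratio is the absolute median difference over the span of
  all whiskers.

## Synthetic data

The generator targets the qualitative signatures the features exploit,
not airway physiology. Normal breathing is Gaussian noise through a
first-order 600 Hz low-pass (≈ −6 dB/octave) under a raised-cosine
breath envelope. A wheeze adds 1–2 sinusoids with centre frequency
drawn from 150–1000 Hz, slow sinusoidal FM (default depth 30 Hz at
1 Hz), a tonal span of at least 80 ms (default 60–100% of the event),
and amplitude set to a tone-to-background ratio in dB (default +10 dB).
Default dataset structure: 38 recordings of 11–12 events (~425 events,
~52% wheeze, durations 0.3–1.5 s) written at 44.1 kHz so the resampling
path is exercised. Event labels are drawn independently per event, so
recordings are label-mixed and recording-level splits almost surely
retain both classes on both sides.

What passing the end-to-end benchmark shows: the pipeline preserves and
detects narrowband tonal structure against breathing-like noise, ranks
tonality-sensitive features at the top, and does so without leakage.
What it does not show: performance on real auscultation, which adds
crackles, heart-sound residues, transmission-path colouring, sensor
variety and annotation noise — none of which the generator models. On
the synthetic conditions several features saturate (AUC = 1.0), so the
benchmark discriminates feature *families* more than it resolves fine
rank order among the top features.

## Problem sizes

The acceptance script uses the default dataset (~425 events), 20
repetitions for the repeated single-feature benchmark, and 5
repetitions over the top-10-by-AUC pool for the logistic pair search —
sizes chosen to make the whole recomputation a sub-minute, single-CPU
run while keeping Monte-Carlo noise well below the decision margins it
reports.

## Known limitations

* The evaluation sweeps one threshold per feature; no per-segment
  majority voting, SVM/ANN/GMM classifiers, or MFCC deltas.
* No confidence intervals on AUC and no multiple-testing correction
  across the 105 rank-sum tests.
* The timing profile is a relative ranking only; absolute times are
  hardware- and implementation-dependent.
* Wheeze simulation covers monophonic/biphonic tonal wheezes only — no
  crackles or stridor.
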