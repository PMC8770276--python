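# Methods

## Problem and scope

`eegpref` implements an end-to-end analysis for decoding a binary
consumer preference (like = 1 / dislike = 0) from multichannel EEG
recorded while a participant views product images. The study design it
targets: 15 participants, 25 runs each, 22 Ag/AgCl electrodes of the
10–20 system sampled at 500 Hz, each run 11 s (2 s fixation cross, 8 s
product display, 1 s rest), with a keyboard response during the display
window providing the label. Because raw recordings from such studies
are rarely shareable, the package ships a first-class synthetic-data
generator that emulates the protocol and carries controllable class
effects, so every downstream stage is testable and the whole analysis
is reproducible from a seed.

## Signal model of the generator

Each run is synthesized per channel as

    x(t) = g_subj · [ b(t) + Σ_band A_band · m_band(t) · osc_band(t) ] + ε(t)

* `b(t)` — background noise spectrally shaped to 1/f^exponent
  (default exponent 1.0, sd 10 µV), the dominant broadband component
  of resting EEG.
* `osc_band(t)` — a unit sinusoid at the band's center frequency
  (δ 2.25, θ 6, α 10.5, β 21.5 Hz) with random phase; amplitudes
  `A_band` default to δ 8, θ 6, α 10, β 4 µV. A sinusoid of amplitude
  A carries band power A²/2, so injected effects have closed-form
  expectations.
* `m_band(t)` — 1 outside the stimulus window; inside it, the
  class-dependent gain of any effect covering that band/channel. On
  like trials a left/right asymmetry `asym_delta` additionally scales
  left-hemisphere channels by (1 − δ) and right by (1 + δ).
* `g_subj` — a per-subject lognormal amplitude scale
  (`subject_gain_sd`, default 0.02; see *Exchangeability* below).
* `ε(t)` — white sensor noise (sd 2 µV).

Labels are i.i.d. Bernoulli(`like_prob` = 0.5) per run. Event markers
are placed at 0 s (fixation), 2 s (stimulus onset), uniformly within
the display window (response, code matching the label), and 10 s
(rest). An optional eye-blink model adds positive half-cosine
transients (~400 ms), maximal prefrontally; the default artifact rate
is zero and artifact *correction* is deliberately out of scope (a
`clean_fn` hook lets users plug an external cleaner between filtering
and epoching).

### Exchangeability by construction (grains)

The analysis classifies 1.33-s sub-segments pooled across runs and
subjects, with stratified folds that may place sub-segments of one run
on both sides of a split. Any random quantity drawn once per run — a
whole-run background realization, a run-wide oscillator phase, a large
per-subject amplitude — stamps all six sub-segments of that run with a
common fingerprint. A nearest-neighbour classifier then recovers run
identity, and with it the label, far above chance even when no class
effect exists (we measured up to ~99% "accuracy" with zero effects for
a naive run-coherent synthesis). Since the generator's purpose is to
calibrate the statistical pipeline, its null condition must be
genuinely exchangeable at the segment level.

Both the background and the oscillators are therefore synthesized from
independent *grains* joined by 8-ms power-preserving (sin/cos)
crossfades, with grain boundaries aligned to the sub-segment grid the
default analysis induces (segments of 341/256 s inside the display
window). Each analysis segment maps onto exactly one independent
realization; the only random mass shared between neighbouring segments
is the few-millisecond crossfade plus the unavoidable smear of the
preprocessing filters. The per-subject gain is kept small by default
(lognormal sd 0.02) for the same reason: realistic inter-subject
amplitude spreads (sd ≥ 0.2) make same-subject segments cluster in
feature space, which re-weights nearest-neighbour pools toward the
test segment's own run and biases pooled-CV null accuracy upward by
1–3 points. Users studying subject heterogeneity can raise
`subject_gain_sd`; the pooled-CV exchangeability guarantees then no
longer hold, which is itself a faithful reproduction of a real
limitation of pooled segment-level cross-validation.

What the generator does *not* model: volume conduction (channels are
independent up to re-referencing), non-stationary rhythms, muscle or
line-noise artifacts, response-locked dynamics. Passing tests on this
synthetic data therefore demonstrate correctness and calibration of
the *pipeline*, not expected accuracy on real recordings.

### Calibrated default effects

Neither effect sizes nor their exact topography are fixed by the study
design, so defaults were calibrated once so that the parameter-recovery
suite passes with margin, and then frozen:

| band  | channels      | like gain | asym δ |
|-------|---------------|-----------|--------|
| alpha | O1, O2        | 2.6       | 0.25   |
| alpha | frontal (8)   | 1.8       | 0.25   |
| beta  | O1, O2        | 1.6       | —      |
| beta  | parietal (5)  | 1.45      | —      |
| theta | T7, T8        | 1.55      | —      |
| theta | frontal (8)   | 1.4       | —      |
| delta | T7, T8        | 1.5       | —      |
| delta | frontal (8)   | 1.4       | —      |

The strongest contrast sits in occipital alpha; every band carries
some effect (consistent with significant power differences observed in
all four bands in this kind of study), and the central region is left
effect-free as a negative control. Effects in all bands are necessary
for fusion behaviour: with a single informative band, concatenating
the other bands only dilutes KNN distances and fusion *loses* to the
best single band, whereas distributed effects reproduce the expected
pattern (fusion ≥ best subset). Temporal effects sit on T7/T8, never
on the mastoids: TP9/TP10 are the offline reference, so any effect
placed there would propagate into all 22 re-referenced channels and
smear the intended topography across the whole head.

## Preprocessing

Fixed stage order (stages skippable, never reorderable):

1. **Re-reference** to the mean of the bilateral mastoids TP9/TP10.
2. **Band-pass** 0.5–40 Hz, order-4 Butterworth, applied
   forward–backward (zero phase; effective order 8). Phase distortion
   would move oscillatory energy between the sub-segments that later
   become classification samples, so zero-phase filtering is the
   appropriate offline choice.
3. **Epoch extraction**: one 0–8 s stimulus-locked window per run;
   the response marker supplies the label. Windows are half-open,
   sample indices 0-based.
4. **Downsample** to 256 Hz by polyphase rational resampling
   (anti-aliased; band powers below 40 Hz preserved to ≲3%).
5. **Segmentation**: each 2048-sample epoch splits into 6 equal
   non-overlapping contiguous segments of 341 samples (floor division,
   2 trailing samples discarded). Non-overlapping equal splits are an
   interpretation — the arithmetic 375 epochs × 6 = 2250 samples only
   fixes the count, not the overlap — and the segment count is a
   config parameter.

## Features

All logs are natural; differential entropy is in nats (base-2
available via an argument).

* **Relative band power** (`psd`): Welch PSD (1-s Hamming windows, 50%
  overlap; the window shrinks to the segment length with a logged
  notice — for 341-sample segments this is a single modified
  periodogram with ~0.75 Hz resolution, the limit at the δ band's
  0.5 Hz edge), integrated over δ/θ/α/β and normalized by the sum of
  the four band powers, so each channel's four shares sum to 1. The
  normalizer deliberately omits the unused 30–40 Hz residual; absolute
  band power is available behind a flag.
* **Asymmetry indices** (`asymmetry`), from absolute band powers:
  approach–withdrawal (α(F4)−α(F3))/(α(F4)+α(F3)); effort, the same
  form on θ; valence α(F4)/β(F4) − α(F3)/β(F3); choice index
  (ln L − ln R)/(ln L + ln R) per homologous left/right pair and band.
  The 16-channel choice configuration uses the 8 non-reference pairs
  of the default montage (TP9/TP10 are the offline reference and are
  excluded). Indices with non-positive inputs raise a domain error; a
  vanishing choice-index denominator raises an undefined-feature
  error — NaN never enters a feature table silently.
* **Differential entropy** (`de`): band-pass the segment (order-4
  zero-phase Butterworth) and return ½·ln(2πeσ²) with σ² the sample
  variance — the Gaussian closed form, making DE a log-variance
  feature per (channel, band).
* **Hjorth parameters** (`hjorth`), computed per band on the
  band-filtered signal so band ablations are meaningful: activity
  (variance, µV²), mobility √(var s′/var s) (rad/s), complexity
  mobility(s′)/mobility(s) (≈1 for a pure tone). The derivative is the
  forward first difference × fs; this biases mobility of an f-Hz tone
  to 2·fs·sin(πf/fs) — within 1% of 2πf below ~20 Hz at fs 256 and
  1.6% low at 25 Hz.

## Statistics

Per (channel, band), relative band powers of like vs dislike segments
are contrasted with a two-sided two-sample t-test (Welch
unequal-variance by default; pooled available). No multiplicity
correction by default — the map mirrors raw p ≤ 0.05 topographies —
with optional Benjamini–Hochberg adjustment. The unit of analysis is
the pooled segment; segments of one subject are not independent, so a
`per_subject` mode tests subject-level class means instead. The pooled
default is faithful to the emulated design, not a statistical
endorsement.

## Classification and ablations

Four classifiers: KNN with Euclidean or cosine distance (k = 5 — odd,
tie-free for binary labels; the emulated study states no k) and SVM
with RBF or polynomial kernel (C = 1, gamma scaled by 1/(d·var),
degree 3 — likewise unstated, exposed in config). Features are
z-scored by the training fold's mean/sd only. Evaluation is repeated
stratified shuffled 10-fold CV of pooled segments; accuracy is
100·n_correct/n_total per fold, and the reported figure is the mean
over repetitions × folds. Ablations (per region + whole head, per band
+ all bands, eight named feature configurations) share fold partitions
via a common seed so comparisons are paired. An epoch-grouped CV mode
keeps each run's segments on one side of every split; it is the
leakage-free variant and typically scores lower than the pooled
default.

## Numerical and design choices

* Band integrals use the trapezoid rule with endpoint interpolation,
  so a flat density yields shares exactly proportional to bandwidth.
* Welch uses Hamming windows and the standard one-sided density
  normalization.
* Degenerate inputs raise typed errors (`DomainError`,
  `UndefinedFeatureError`, `ClassBalanceError`, …) rather than
  propagating NaN.
* Stratified partitions that leave a single-class training fold are
  re-drawn (logged), failing after 10 attempts.
* The internal fixture container is a NumPy `.npz` archive (bit-exact
  float round trip, unlike CSV); BrainVision and EDF inputs are read
  through MNE with a user-supplied marker code map, since vendor
  marker strings vary.
* Determinism: one seed drives label draws, subject gains, per-run
  substreams (derived from (seed, subject, run), so single runs are
  reproducible in isolation), and CV partitions. Identical config +
  seed reproduces every CSV/JSON artifact byte-for-byte.

## Problem sizes used by the test and acceptance suites

The structural checks and null calibration run the full default design
(15 × 25 = 375 runs, 2250 segments). Null accuracy per
classifier/ablation cell is the mean over five independent zero-effect
datasets: single-dataset cross-validation estimates carry
dataset-realization variance (sd ≈ 1 accuracy point for small feature
subsets) well beyond the binomial term, and replication — not a wider
tolerance — is the appropriate remedy. Parameter recovery uses twenty
datasets of 6 subjects × 25 runs at 3 × 10-fold CV, which preserves
the per-subject run count (and hence the pooled-CV geometry) while
keeping the suite fast; p-value uniformity pools 12 small null
datasets (≥ 1000 cells). The acceptance script runs the full design
with 3 × 10-fold CV.

## Known limitations

* No volume conduction or correlated channel noise; spatial structure
  beyond region membership is absent.
* ICA-based artifact correction is not implemented; the blink injector
  exists to exercise external cleaners, not to validate correction.
* The pooled segment-level CV protocol — reproduced here as the
  default because it is the emulated study's protocol — is
  optimistic on data with run- or subject-level structure; the
  epoch-grouped mode and per-subject statistics exist precisely
  because of that caveat.
* Welch resolution (0.75 Hz at the default segment length) makes the
  δ band's 0.5 Hz edge approximate.
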