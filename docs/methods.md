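# Methods

This note documents the models, algorithms and design choices behind
`pdvoice`: a pipeline that screens for Parkinsonian hypokinetic
dysarthria from speech using cepstral features, and that is exercised
end-to-end on a synthetic voice cohort with known ground truth.

## 1. The screening problem

Hypokinetic dysarthria — the speech disorder of Parkinson's disease
(PD) — manifests acoustically as reduced pitch variability (monopitch),
elevated cycle-to-cycle perturbation of vocal-fold period (jitter) and
amplitude (shimmer), and a reduced harmonics-to-noise ratio (HNR).
These changes alter the short-time spectral envelope, which is what
cepstral coefficients summarise.  The pipeline therefore: (1) extracts
13 mel-frequency and 13 gammatone-frequency cepstral coefficients
(MFCC/GTCC) per fixed-length audio sample, (2) for phone conversations,
first isolates the subject's voice by speaker diarization, (3) trains
three classifier families on balanced tables under nested
cross-validation, and (4) tests each coefficient for an HC-vs-PD group
difference.

## 2. Synthetic voice model

Real dysarthric recordings cannot ship with a package; instead the
`synth` module generates voices from a source–filter scheme whose
pathology knobs are *exactly controllable and re-measurable*:

* **Glottal source** — an impulse train.  A pitch target is drawn per
  0.5 s voicing segment from Normal(`f0_mean`, `f0_sd`); each cycle's
  period is perturbed by Normal(0, `jitter_pct`/100 × period) and
  rounded to samples, each cycle's amplitude by
  Normal(0, `shimmer_pct`/100).  Jitter and shimmer are thus, by
  construction, the coefficients of variation of the inter-pulse periods
  and pulse amplitudes — measurable from the pulse train by peak
  picking, which is how the tests verify recovery (±0.5 percentage
  points at 2 % jitter; ≤25 % relative over 20 seeds).
* **Aspiration noise** — white noise mixed into the source at the
  requested HNR (power ratio); `hnr_db=None` disables it.
* **Vocal tract** — a cascade of second-order resonators at the
  configured formants (default 500/1500/2500 Hz, neutral vowel); output
  peak-normalised to 0.9.

An impulse train was chosen over an analytic glottal-flow model because
perturbation parameters enter it exactly; realism beyond the spectral
envelope is not the goal (see §8).

**Class defaults.**  HC: jitter 0.5 %, shimmer 3 %, HNR 20 dB, f0 sd
15 Hz.  PD: jitter 2 %, shimmer 8 %, HNR 10 dB, f0 sd 4 Hz (monopitch).
These sit in the ranges dysarthria literature typically reports for
sustained phonation in controls vs moderate PD; they are package
configuration, not claims about any particular cohort.  Per-speaker
scatter (±10 % f0, ±15 % perturbations, ±6 % vocal-tract scale) makes
cohorts overlap rather than be trivially separable.

**Conversations** concatenate per-turn syntheses of two speaker specs
with 0.25 s silent gaps and no additive noise (emulating a recording
taken directly on the line), and return the exact speaker timeline.

## 3. Signal conditioning and cepstral features

Defaults follow common speech-analysis practice and are all
configurable: pre-emphasis α = 0.97; 25 ms Hamming frames at 10 ms hop;
recordings cut into non-overlapping 1.0 s samples (trailing remainders
discarded rather than zero-padded, keeping sample lengths uniform).

Both cepstral front-ends share one pipeline: power spectrum (FFT at the
next power of two) → filterbank energies → log (floored at 1e−10 to
guard silence) → orthonormal type-II DCT → first 13 coefficients.

* **MFCC** — 40 triangular filters with apexes equally spaced on the
  HTK mel scale, 2595·log10(1 + f/700), between 50 Hz and Nyquist.
* **GTCC** — 40 fourth-order gammatone filters with centers equally
  spaced on the ERB-rate scale, 21.4·log10(1 + 0.00437 f).  Filters are
  realised as sampled frequency-domain power responses
  (1 + ((f−fc)/b)²)⁻⁴ with b = 1.019·ERB(fc), which gives the classical
  3-dB width 0.887·ERB(fc).  Realising them on the FFT grid (instead of
  time-domain IIR filtering) lets GTCC share the MFCC code path and the
  same brute-force test oracle; time-domain equivalence is not claimed.

The 13 coefficients include the 0th (log-energy) coefficient; a sample's
feature vector is the per-coefficient mean over its frames (median
available).  Both choices are conventions, flagged as configurable
because the field uses several.  Correctness is anchored by an
independent oracle: a naive O(N²) DFT sum with explicitly constructed
filterbank and DCT matrices must agree with the FFT pipeline to 1e−8
relative on random frames.

**Normalisation** is per-column z-scoring with the *training* table's
mean/sd applied to the test table — the leakage-free choice; a global
mode exists for comparison.

## 4. Speaker diarization

Two-party calls are cut into 1.0 s windows at 0.5 s hop; each window is
embedded as the per-window mean ⊕ standard deviation of its 13 frame
MFCCs (26 values).  The embedder is a pluggable strategy — a neural
speaker embedding (x-vector) could be registered in its place — but on
clean, noise-free calls spectral statistics separate two speakers well.

Clustering is Lloyd k-means with greedy farthest-point seeding,
restarted 8× from derived seeds keeping the best within-cluster sum of
squares.  k equals the speaker count, plus one when a noise cluster is
requested (that cluster, identified as the one with lowest mean energy,
is excluded from speaker export).  Three choices matter in practice and
were made after observing failure modes on synthetic calls:

1. Embedding dimensions are standardised before clustering; otherwise
   the large-magnitude energy coefficient dominates the metric.
2. The sd half of the embedding is down-weighted (×0.2): windows
   straddling a turn change mix two voices and a gap, inflating their
   sds, and at full weight those boundary windows out-cluster the
   speakers themselves.
3. Window labels are smoothed by a *recursive* sliding majority vote
   (preceding positions contribute their already-smoothed label, ties
   fall to the preceding label).  The recursive form reaches a fixed
   point in one pass on binary sequences, making smoothing idempotent.

Segment boundaries are then refined at hop resolution: each 0.5 s
stride is embedded itself and assigned to the nearest cluster centroid
(computed from the smoothed window labels).  Assigning strides from
whole-window labels instead would quantise every speaker change to
±0.5 s and cap agreement near 90 % on short turns; stride-level
assignment reaches 97.9 % time-weighted agreement (after optimal label
permutation) on all ten default synthetic conversations, with 100 %
subject purity.  The residual ~2 % is boundary quantisation inside the
silent gaps, which carry no reference label.

## 5. Classification protocol

Three fixed model families: cubic SVM (polynomial kernel, degree 3,
one-vs-one decision scheme — retained although the task is binary, where
it degenerates to a single machine), 1-nearest-neighbour with Euclidean
distance, and a "wide" neural network with one hidden layer of 100
rectified units (lbfgs, seeded initialisation, 400-iteration cap).

Nested stratified 5×5-fold cross-validation: the inner loop selects the
hyperparameter — SVM margin penalty C ∈ {0.1, 1, 10}; network ridge
penalty α ∈ {1e−4, 1e−2, 1}; 1-NN has nothing to tune, its inner loop
degenerates and is recorded as such — on each outer-training portion
only; the outer loop estimates generalisation.  The final model refits
on the full training table with the majority-vote choice (ties to the
smallest value) and is evaluated exactly once on the held-out table.
Fold bookkeeping is returned with every report so the no-leakage
property is asserted programmatically, and feature tables track column
access so a single-feature-set run provably never reads the other set.

Training accuracy is reported as the mean outer-fold training-portion
accuracy (resubstitution on the full table is available by flag).
Metrics treat PD as the positive class: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), F1 = 2TP/(2TP+FP+FN).

**Tables** are balanced by drawing equal per-class row counts without
replacement.  The default draw is at the sample level, so samples of
one speaker can land in both train and test — an optimistic-bias risk
the audit always reports; `subject_disjoint=True` assigns whole
speakers to one side instead.

## 6. Group inference

Per coefficient, an unpaired two-sample t-test between the HC and PD
feature distributions; Student (pooled variance, df = nₐ+n_b−2) by
default, Welch available and preferable under unequal variances.  Stars
follow the conventional thresholds (\*, \*\*, \*\*\*, \*\*\*\* at 0.05,
0.01, 0.001, 0.0001).  Because 26 tests invite multiplicity, a Holm
step-down mode is provided and both raw and corrected p are always
written side by side; the default annotation is uncorrected.  The
implementation is the closed-form statistic with the t distribution for
tails; tests cross-check it against an independent library routine and,
for tiny samples, against exact permutation enumeration.

## 7. Problem sizes and verification

Verification runs use deliberately modest sizes chosen to exercise every
code path with adequate statistical power: ten 13 s two-speaker calls
for diarization; 26-dimensional Gaussian feature cohorts (6 sd class
separation for the learnable case, permuted labels for the chance case,
20 seeds at test n = 40); 500 replicates of a 50-vs-50 same-distribution
null for t-test calibration, asserting the rejection rate pooled across
the 26-coefficient panel lies in [0.03, 0.07] (a single coefficient's
rate over 500 replicates has binomial sd ≈ 0.01, too noisy to bound that
tightly per coefficient); and ten 50 HC / 50 PD synthetic cohorts (2 s
recordings, 160/40 tables) for the end-to-end comparison of MFCC-only,
GTCC-only and combined features.  The analysis scripts scale the same
experiments up to study-sized tables (3000/300 reading, 400/40
conversation).

## 8. What the synthetic cohort does and does not show

The generator produces sustained-phonation-like signals with controlled
pathology acoustics and clean two-speaker turn-taking.  It does not
model articulated speech (phones, prosody, coarticulation), channel
effects, background noise, overlapped speech, or within-session drift.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct — features measure the spectral envelope faithfully, diarization
recovers known timelines on clean audio, the CV protocol is leak-free,
inference is calibrated — and that the advertised class differences are
detectable when present.  They do not establish clinical accuracy on
real voices; accuracies on the synthetic cohort reflect the configured
class gap, not a clinical effect size.  Real recordings can be run
through the same pipeline via the CLI (`pdvoice features`,
`pdvoice diarize`), with results expected to be lower and
dataset-dependent.

## 9. Numerical details

* All randomness flows through per-call `numpy` generators seeded
  explicitly; no global RNG state.  Sub-seeds are derived arithmetically.
* Log energies are floored at 1e−10; silence yields a constant log
  spectrum whose DCT is all-zero beyond coefficient 0.
* k-means ties (equidistant points) resolve by lowest cluster index via
  argmin; 1-NN distance ties and network probability ties resolve by
  lowest class index (library convention).
* WAV I/O is 16-bit PCM, scaled by 32768 so the most negative code is
  exactly −1.0; round trips are bit-exact.  Rate mismatches are handled
  by polyphase rational resampling and logged.
* Degenerate t-test inputs (both groups constant and equal) return
  t = 0, p = 1 rather than erroring.
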