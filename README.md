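# pdvoice

Cepstral speech biomarkers for Parkinson's disease screening.

Parkinson's disease produces a characteristic speech disorder —
hypokinetic dysarthria: monotone pitch, elevated cycle-to-cycle jitter
and shimmer, a noisier glottal source.  These changes leave measurable
fingerprints in the short-time spectral envelope, which cepstral
coefficients summarise compactly.  `pdvoice` implements a complete
screening pipeline for researchers working on digital voice biomarkers:

* **Features** — 13 mel-frequency (MFCC) and 13 gammatone-frequency
  (GTCC) cepstral coefficients per 1 s audio sample, computed through a
  shared pipeline: pre-emphasis → 25 ms Hamming frames → power spectrum
  → filterbank (mel triangles / 4th-order gammatone responses on the
  ERB-rate scale) → log → orthonormal DCT-II, then z-scored with
  training-set statistics.
* **Speaker diarization** — for two-party phone conversations, k-means
  clustering of per-window cepstral-statistics embeddings with label
  smoothing isolates the subject's voice from the interviewer's before
  any feature is extracted ("who spoke when").
* **Classification** — cubic SVM (one-vs-one), 1-nearest-neighbour
  (Euclidean), and a wide neural network (one hidden layer of 100
  units), each evaluated on MFCC-only, GTCC-only and combined features
  under nested 5×5-fold cross-validation on class-balanced tables, with
  accuracy, sensitivity, specificity, F1 and confusion matrices (PD is
  the positive class).
* **Group inference** — an unpaired t-test per coefficient between the
  HC and PD distributions, with conventional star annotation and an
  optional Holm correction.
* **Synthetic cohort** — a source–filter voice generator whose jitter,
  shimmer, HNR and pitch-variability knobs are exactly controllable and
  re-measurable, plus two-speaker conversation synthesis with exact
  ground-truth timelines.  Every stage is testable end-to-end without
  any external recordings.

## Worked example

Run the conversation-task experiment on a synthetic cohort (20 HC and
20 PD subjects, each in a phone-style dialogue with a healthy
interviewer; diarize → extract subject speech → featurize → balanced
400/40 tables → model grid → t-tests):

```sh
python analysis/03_conversation_task.py
```

which prints (seed 0):

```
feature_set     model  training_accuracy_pct  outer_cv_accuracy_pct  test_accuracy_pct  sensitivity  specificity  f1_score
       mfcc cubic_svm                  97.50                  95.00               97.5         1.00         0.95      0.98
       mfcc      knn1                 100.00                  96.50               97.5         0.95         1.00      0.97
       mfcc   wide_nn                  99.00                  96.50               97.5         1.00         0.95      0.98
       gtcc cubic_svm                  98.69                  97.00               97.5         1.00         0.95      0.98
       gtcc      knn1                 100.00                  97.00               97.5         0.95         1.00      0.97
       gtcc   wide_nn                  99.69                  96.25              100.0         1.00         1.00      1.00
       both cubic_svm                  98.62                  96.25               97.5         1.00         0.95      0.98
       both      knn1                 100.00                  97.00               97.5         0.95         1.00      0.97
       both   wide_nn                  99.81                  96.75              100.0         1.00         1.00      1.00

coefficients with p < 0.01 between HC and PD: 6 / 26
```

Each row is one feature set × model cell: training accuracy is the mean
outer-fold training accuracy of the nested CV, test accuracy is measured
once on the held-out 40-sample table, and sensitivity/specificity treat
PD as the positive class.  The high absolute numbers reflect the
configured synthetic class gap, not a clinical effect size; what carries
over to real data is the machinery, not the accuracy (see
`docs/methods.md`).  The t-test line says that 6 of the 26 cepstral
coefficients differ between the diarized HC and PD cohorts at p < 0.01.

The other drivers: `analysis/01_simulate_cohort.py` (generate the
cohort and verify jitter/shimmer recovery), `analysis/02_reading_task.py`
(single-speaker reading task, 3000/300 tables),
`analysis/04_group_inference.py` (full t-test panel with a
cumulative-distribution figure).  All tables land under `results/`.

There is also a CLI for real recordings:

```sh
pdvoice synth --n-hc 2 --n-pd 2 --out wavs/        # synthetic WAVs
pdvoice features wavs/*.wav --label HC --out f.csv # 26-column table
pdvoice diarize call.wav --out diar/               # RTTM + per-speaker WAVs
pdvoice fetch-mdvr                                 # where to get real data
```

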