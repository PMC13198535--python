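# spindlekit

Automated end-to-end sleep-spindle analysis for EEG: stage-aware
preprocessing, a trainable 1-D U-Net spindle segmenter, event- and
epoch-level agreement metrics, spindle characteristics, cohort statistics,
and a synthetic-EEG generator with planted ground truth.

## The problem

Sleep spindles — transient 10–16 Hz oscillatory bursts of ~0.3–2.5 s,
hallmark of N2 non-REM sleep — are scored by hand in most sleep studies,
which is slow and suffers from substantial inter-rater variability.
Automating the analysis requires *two* coupled steps: sleep staging (30-s
epochs labeled W/N1/N2/N3/REM), and spindle detection restricted to the N2
epochs, because detectors applied without stage restriction report spindles
in Wake and REM where they are biologically implausible.  spindlekit
implements the full chain for researchers who want to run, train, or
stress-test such a pipeline, and to compare model–scorer agreement against
inter-rater agreement.

## What's inside

* **Staging scaffolding** — any per-epoch stage-probability predictor plugs
  in behind one contract; the recording is zero-buffered with 20 epochs,
  a 21-epoch window slides with step 1 (each epoch covered by exactly 21
  windows), and the per-epoch probabilities are aggregated by their
  geometric mean.  A trainable spectral baseline (band powers + multinomial
  logistic regression) ships for end-to-end testing.
* **Spindle segmenter** — a U-Net with two encoder and two decoder blocks
  mapping an arbitrary-length preprocessed block to two per-sample score
  masks; runs of spindle-class samples become events.  Trained with Adam
  (batch 12, lr 0.005), a generalized Dice loss (robust to the extreme
  class imbalance), amplitude-rescaling augmentation (×U(1,2) or
  ×U(0.5,1), fair coin) and early stopping on validation IoU-F1.
  Implemented in NumPy; seeded runs are reproducible on one CPU.
* **Event metrics** — the IoU-F1 agreement score: detections are matched to
  the temporally closest reference events, a pair counts as a true positive
  when intersection/union > 20%, counts pool across recordings, and
  IoU-F1 = 2·TP/(2·TP+FP+FN).  Epoch-level agreement uses the macro F1
  over the five stages.
* **Characteristics** — per-spindle duration, dominant frequency (mean of
  zero-crossing instantaneous frequencies of the 10–16 Hz band-passed raw
  signal), amplitude (mean Hilbert envelope), density (spindles per minute
  of N2), and the fast (>13 Hz) / slow (≤13 Hz) split; plus Welch /
  rank-sum cohort comparison tables.
* **Synthetic data** — Markov hypnograms, 1/f-type background with
  stage-dependent rhythms, Gaussian-enveloped spindles planted in N2 at
  configurable density/duration/frequency/amplitude, simulated imperfect
  raters, and two-cohort study generation.  See `docs/methods.md`.

## Worked example

Train the segmenter on 40 synthetic high-SNR N2 blocks and score held-out
blocks at three amplitude scales (`examples/02_train_and_detect.py`):

```
trained 60 epochs; best validation IoU-F1 = 1.000
held-out IoU-F1 at amplitude x1.0: 1.000
held-out IoU-F1 at amplitude x0.5: 1.000
held-out IoU-F1 at amplitude x2.0: 0.977
```

The validation IoU-F1 of 1.000 says every planted spindle in the held-out
blocks was matched above the 20% overlap threshold with no false positives;
the near-identical scores at half and double amplitude show the rescaling
augmentation doing its job — detection quality barely depends on the
recording's amplitude scale.

Compare two synthetic cohorts at published-scale parameters
(`examples/04_cohort_comparison.py`, n = 20 per cohort):

```
cohort A fast density: 3.50 (1.49) SPM
cohort B fast density: 2.50 (1.07) SPM
welch test p-value: 0.0206
```

Cohort A was generated at 3.43 ± 1.70 spindles per minute (SPM) of N2 and
cohort B at 2.15 ± 1.46; the recovered means (± SD across subjects) track
the generator settings within sampling error, and the density gap is
detected by Welch's t-test.

The other examples cover synthetic-study generation, baseline staging
(macro F1 printed against the true hypnogram), and simulated inter-rater
agreement tables.  A thin CLI wraps the same library calls:

```bash
spindlekit synth --subjects 4 --epochs 120 --seed 7 --out study/
spindlekit train-spindle --data study/ --seed 7 --out model.npz
spindlekit detect --edf study/subject00.edf \
    --hypnogram study/subject00_stages.csv --checkpoint model.npz \
    --out events.csv
spindlekit evaluate spindles --ref study/subject00_truth.csv --pred events.csv
```

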