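# Methods

This note documents the models and procedures implemented in spindlekit, the
parameters that matter, the synthetic-data model used for testing, and the
design choices that were genuinely open.

## Analysis pipeline

The toolkit automates the two-step analysis commonly used for sleep
microstructure: first the overnight EEG is staged into 30-s epochs
(W/N1/N2/N3/REM), then sleep spindles are detected inside the N2 sleep only,
because spindle detectors are trained on N2 data and produce biologically
implausible detections in Wake or REM when applied without stage
restriction.  The package exposes all three variants: detection on expert
stages, detection on automatically predicted stages, and (off by default)
stage-unaware detection that reproduces the failure mode.

### Preprocessing

Two chains, both zero-phase (forward–backward, second-order sections):

| step | staging chain | spindle chain |
|---|---|---|
| filter | Butterworth band-pass 0.3–30 Hz, order 4 | Butterworth high-pass 0.3 Hz then low-pass 30 Hz, both order 20 |
| rate | resampled to 60 Hz | resampled to 100 Hz |
| scaling | median/IQR robust normalization, clipped at ±20 | same |

Design points: zero-phase application is standard sleep-EEG practice and is
required here so event boundaries are not phase-shifted (the timing property
is tested: a sigma burst's envelope peak moves < 50 ms through the chain).
The stated orders are the one-way design orders, so effective attenuation is
doubled.  Order-20 designs are only stable in SOS form; the implementation
refuses to return non-finite output.  Quantiles use linear interpolation
(type 7).  Normalization is computed per N2 block for the spindle chain and
per whole recording for the staging chain, mirroring each model's input
unit; which unit the normalization should use was an open choice.
Resampling is polyphase FIR; only downsampling is supported because both
chains band-limit explicitly before reducing the rate.

### Staging scaffolding

Any per-epoch stage-probability predictor can be plugged in.  The recording
is buffered with 20 zero epochs at each end; a 21-epoch window slides with
step 1, so each real epoch is covered by exactly 21 windows; the 21
probability vectors per epoch are combined by a per-stage geometric mean
(probabilities floored at 1e-12 before the log) and renormalized.  Argmax
ties break toward the earlier stage in W < N1 < N2 < N3 < REM order, making
output deterministic.  A trainable baseline predictor (Welch band powers in
delta/theta/alpha/sigma/beta, averaged over channels, followed by
multinomial logistic regression) ships with the package so the scaffolding
can be exercised and tested end to end without external checkpoints;
pre-trained staging networks remain pluggable behind the same contract and
are deliberately not re-implemented.

### Spindle segmenter

A 1-D U-Net with two encoder and two decoder blocks maps a preprocessed
single-channel block of arbitrary length to two equal-length score masks
(spindle / non-spindle); per-sample class is the per-sample maximum, and
maximal runs of spindle samples become candidate events.  Defaults recorded
in `UNetConfig`: 16 base filters (doubling per level), kernel size 5,
pooling factor 2, two convolutions + ReLU per block, nearest-neighbour
upsampling with skip concatenation.  Inputs are internally zero-padded to a
multiple of 4 and the output cropped, so any length ≥ 4 samples is
admissible.  The network and its backpropagation are implemented directly
in NumPy (im2col convolutions over BLAS); single-threaded CPU runs are
bitwise reproducible per seed, multi-threaded runs only statistically so.

Training: Adam (lr 0.005), batch size 12, generalized Dice loss with class
weights w_c = 1/(Σ target_c + ε)², ε = 1e-6 — the inverse-squared class
frequency makes the loss robust to the extreme spindle/background
imbalance.  Variable-length blocks are zero-padded to the batch maximum
with a sample mask excluded from the loss.  Each training sample is
amplitude-augmented: a fair coin picks upscaling (factor ~ U(1, 2)) or
downscaling (factor ~ U(0.5, 1)), teaching robustness to amplitude-scale
differences between recordings and subject groups.  Early stopping monitors
the validation IoU-F1 (10% of blocks held out by default) with patience 300
within at most 800 epochs; "epoch" means a full pass over the training
blocks.  Among epochs tying the best validation score the most recent
weights are kept (ties do not reset patience): on benchmarks where the
validation score saturates early, the first tied epoch is undertrained and
not yet amplitude-robust, while later tied epochs are.  Returned history
records per-epoch loss and validation IoU-F1.

The six-fold cross-validation and hyperparameter search used to develop the
original detector are out of scope; a single model is trained with fixed
defaults.

### Event postprocessing and characteristics

Candidate events are postprocessed per channel: neighbours separated by
< 0.1 s are merged when at least one member is shorter than 0.3 s (the rule
rescues fragmented detections; whether *both* members must be short was
ambiguous — requiring one suffices for that purpose), iterated left-to-right
to a fixed point; then events shorter than 0.3 s or longer than 2.5 s are
removed.  The result is idempotent and always inside [0.3, 2.5] s.

For model-vs-reference agreement, events are aggregated across channels by
interval union (transitive closure of strict overlap; touching half-open
intervals stay separate).  Characteristics and densities, in contrast, are
computed separately per channel from that channel's own raw signal — the
per-channel densities of a cohort table cannot come from one union list.

Per spindle, from the raw signal through a 4th-order 10–16 Hz Butterworth
band-pass: frequency is the mean of per-interval instantaneous frequencies,
each 0.5/(zero-crossing interval), crossings located by linear interpolation
(an exact zero sample counts once, at the sample); amplitude is the mean
Hilbert-envelope magnitude over the event, computed with 0.5 s of band-passed
context on each side to suppress Hilbert edge transients; density is events
per minute of N2; the fast/slow split is at 13 Hz (fast strictly above).
Accuracy (tested): < 0.1 Hz on pure sinusoids across 10.5–15.5 Hz, < 3%
amplitude error for 1–50 µV sinusoids.

### Agreement metrics

Epoch level: macro F1 over the five stages, averaging the per-stage F1 over
stages present in either annotation (stages absent from both would give
0/0).  Event level: each detection is matched with the reference event whose
midpoint is closest; the pair is a true positive when intersection/union
exceeds 0.2; each event joins at most one pair (conflicts resolved by larger
IoU, then earlier onset); counts pool by summation across recordings, and
IoU-F1 = 2·TP/(2·TP + FP + FN).  "Temporally closest" admits corner cases,
so a maximum-cardinality-matching mode and a brute-force enumeration oracle
are shipped alongside; the closest-match rule is the default and the max
mode is verified against the oracle on random sets.  Pairwise inter-rater
tables only include scorer pairs sharing at least five jointly annotated
blocks.  The multi-scorer staging consensus is a per-epoch majority vote
with ties broken by the lowest-index scorer — a deliberately simplified
consensus, labeled as such, standing in for the more elaborate published
consensus algorithms whose internals are out of scope here.

Cohort comparison runs one two-sample test per channel × metric cell:
Welch's two-sided t-test by default, switching to the Wilcoxon two-sided
rank-sum test when a Shapiro–Wilk pre-check (α = 0.05, per group) rejects
normality — the published tables do not state their switching criterion, so
this explicit rule was chosen.  P-values are reported raw, without
multiple-testing correction, matching how such tables are presented.

## Synthetic data model

The generator produces what the pipeline consumes — not physiologically
detailed EEG.  Its defaults define the package's study conditions:

* **Hypnogram**: first-order Markov chain with transition matrix
  0.85·I + 0.15·1πᵀ, π = (0.15, 0.07, 0.50, 0.18, 0.10); the stationary
  distribution is exactly π (half the night N2) with mean bout length
  ≈ 6–7 min for N2.
* **Background**: colored noise with amplitude spectrum ∝ 1/f (power
  ∝ 1/f²) over 0.3–45 Hz, total RMS 10 µV — matching the steep spectral
  decay of artifact-free sleep EEG, which leaves ≈ 1 µV RMS in the sigma
  band so the zero-crossing estimator sees spindle-dominated crossings.
  Stage rhythms are band-limited noise added per stage: delta (0.75–2 Hz,
  20 µV) in N3, alpha (8–12 Hz, 6 µV) in Wake, theta in N1/REM.
* **Spindles**: Gaussian-enveloped sinusoids planted only in N2.  The
  nominal duration is the envelope full width at half maximum and the
  ground-truth event is exactly that half-maximum interval — matching the
  visible extent experts annotate.  Durations are truncated normal in
  [0.3, 2.5] s; frequencies truncated to (10, 16) Hz; arrivals are Poisson
  at the requested density with a refractory gap (default 1 s), with a
  warning and the achieved density if the target is unreachable.  Default
  population parameters follow healthy-control frontal fast-spindle
  statistics (3.43 ± 1.70 SPM, 0.87 ± 0.09 s, subject-mean frequency
  13.91 ± 0.14 Hz, within-subject event scatter 0.25 Hz, envelope peak
  8.6 µV ≈ 7 µV mean envelope).
* **Raters**: keep each true event with probability `hit_prob`, jitter
  onset/duration with Gaussians, add Poisson false positives in N2; output
  is overlap-free.  A thinning-only rater has the closed-form pooled
  IoU-F1 = 2h/(2h + (1−h)), used as a calibration check.
* **Cohorts**: per subject, density and mean frequency are drawn from the
  population's between-subject distributions (density truncated at 0), then
  a recording is generated at those subject-level parameters.  All
  randomness flows from one root seed through named substreams.

What passing tests on this model do *not* show: robustness to artifacts,
montage/reference effects, non-Gaussian spindle morphology, or the
covariance structure of real overnight EEG.  The generator is a test bed
for the pipeline's plumbing and estimators, not evidence about clinical
data.

## Problem sizes used in the shipped checks

The training benchmark uses 40 single-epoch (30 s) high-SNR N2 blocks, a
reduced U-Net (8 base filters) and a 60-epoch cap; it must reach validation
IoU-F1 ≥ 0.6 and change by < 0.1 under ×0.5/×2 input rescaling.  The
cohort-recovery checks generate 25-subject cohorts of ~2.3-h nights
(~70 min N2 on average per subject) at the population parameters above;
`scripts/acceptance.py` repeats them over 20 seeds and reports cohort means
of fast-spindle density (frontal and central channel pairs) and dominant
frequency.  These sizes were chosen so the whole battery runs comfortably
on a single CPU while keeping Monte-Carlo error well below the 2-standard-
error acceptance bands.

## Known limitations

* No artifact handling, notch filtering, or montage derivation.
* The baseline stage predictor is a deliberately simple spectral model; it
  is a test vehicle, not a competitive stager.
* EDF writing is minimal (16-bit, 1-s records, integer rates) and intended
  for synthetic exports only; EDF+ annotations are read-skipped, not parsed.
* The NumPy U-Net is CPU-only and sized for desk-scale experiments.
* Event times are half-open float-second intervals; sub-millisecond
  round-trip precision through CSV is not guaranteed (1 ms is).
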