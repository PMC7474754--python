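# Methods

## Problem

In a two-class motor-imagery brain–computer interface, a subject imagines
left- or right-hand movement while EEG is recorded over the sensorimotor
cortex (electrodes C3, Cz, C4 at 250 Hz). Imagery suppresses the mu
(8–14 Hz) and beta (14–30 Hz) rhythms over the hemisphere *contralateral*
to the imagined hand (event-related desynchronization, ERD). A classifier
trained only on the subject's own data (subject-dependent, SD) suffers from
small calibration sets; one trained only on other subjects
(subject-independent, SI) suffers from between-subject variability. The
instance-transfer subject-dependent strategy (ITSD) implemented here
augments the target's training set with *similar* trials from other
subjects, where similarity is measured between spectrogram images by a
perceptual hash.

## Pipeline

1. **Band-pass filter**: Butterworth, order 6, 8–30 Hz, applied to the full
   8 s trial. Application is zero-phase (forward–backward) by default,
   which doubles the effective order but preserves ERD timing; a causal
   single pass is available via `FilterSpec(zero_phase=False)`.
2. **Epoch**: the 3–7 s imagery window, half-open `[start, end)` sample
   indexing (1000 samples at 250 Hz). Filtering precedes epoching so edge
   transients fall outside the analysed window.
3. **Spectrogram**: STFT with a symmetric Hann window of 256 samples and
   224-sample overlap (hop 32, ~24 columns over the epoch; the overlap is a
   package choice to retain temporal resolution ahead of the 64-pixel
   resize). Magnitude-squared power, cropped to the 8–30 Hz pass-band
   (outside it there is only filter roll-off), log10-scaled, then min–max
   normalized to [0, 1] **jointly over the three channels** of the trial.
   Joint (rather than per-channel) normalization is deliberate: the class
   information lives in the C3-vs-C4 power asymmetry, which per-channel
   scaling would erase. A zero-range (constant) power matrix maps to all
   zeros by rule.
4. **Two image views**: the hash consumes a single 64×64 grayscale image
   made by vertically stacking the three channel matrices (C3 top, Cz, C4
   bottom) and resizing bilinearly; the CNN consumes a 64×64×3 tensor with
   one channel per electrode. The third CNN dimension is electrodes, not an
   RGB rendering — a colormap would inject arbitrary, non-reproducible
   structure.
5. **Perceptual hash**: orthonormal 2-D DCT-II of the stacked image; keep
   the 8×8 low-frequency block; threshold each of the 64 coefficients at
   the block mean (ties → 0); flatten row-major into a 64-bit code. The
   mean includes the DC coefficient by default (`exclude_dc=True` gives the
   common variant that drops it). The hash is invariant to positive
   intensity scaling because the DCT is linear.
6. **Transfer weights**: each source trial is scored against the target's
   *matching-class* prototype (the element-wise mean stacked spectrogram of
   the target's training trials of that class; a pooled single-prototype
   mode exists). The Hamming distance d_H ∈ [0, 64] becomes a weight
   w = 1 − d_H/64, so similar trials contribute more. Selection keeps
   trials with d_H ≤ threshold (default 16; 64 = transfer everything,
   weighted; 0 degenerates to SD). The transferred portion is
   class-balanced by keeping the highest-weight trials of the larger class
   (ties broken by subject then trial id); an optional per-source-subject
   cap limits any one subject's influence. Target trials always carry
   weight 1 and are never subsampled.
7. **CNN**: (64,64,3) → conv 3×3, 8 maps, shape-preserving padding, ReLU →
   max-pool 2×2 → conv 3×3, 8 maps, ReLU → max-pool 2×2 → dense 10 (ReLU,
   dropout 0.5) → dense 2 → softmax; 21 320 trainable parameters. Loss is
   per-sample-weighted cross-entropy, `mean_i w_i · CE_i`; the optimizer is
   SGD with momentum 0.9 and per-update learning-rate decay
   `lr / (1 + decay·step)` (decay 1e−6). The network is implemented
   directly in NumPy (shifted-matmul convolutions, argmax-tracked pooling,
   inverted dropout) and its backward pass is verified against central
   finite differences to ~1e−10 in the test suite. Inputs in [0, 1] are
   centred by subtracting the training-set mean, stored with the model;
   without centring, the all-positive inputs stall gradient descent on this
   small network. Parameters are float32 by default (float64 available for
   high-precision checks); training is deterministic given the seed and
   input order, with batched-vs-single predictions agreeing to a few ulp.
8. **Strategies and metrics**: SD and ITSD use seeded *stratified* k-fold
   cross-validation over the target's trials (stratification keeps the
   chance level at exactly 0.5 per fold); SI trains on all other subjects'
   trials and tests on the full target set. ITSD recomputes prototypes and
   transfer weights from each fold's training portion only, so the test set
   can never influence instance selection — the fold objects expose the id
   sets and the tests assert the intersection is empty. Accuracy is
   complemented by kappa = (acc − 0.5)/(1 − 0.5), the chance-corrected
   agreement for a balanced two-class task (a confusion-matrix-estimated
   chance variant is intentionally not the default, since the task is
   balanced by construction).

## Synthetic cohort

No public recording is bundled; all experiments run on a synthetic cohort
that emulates the structure of a standard 9-subject, 3-channel, 250 Hz
cue-paced protocol (720 trials per subject at full scale, balanced classes).
Per trial the generator sums:

* band-limited 1/f background noise (spectral exponent 1, confined to
  ~1–45 Hz with a raised-cosine lower edge and exponential roll-off above
  45 Hz; amplitude `noise_sd`),
* mu and beta sinusoids (amplitudes 1.3 and 0.6 × `noise_sd` at C3/C4,
  0.4× at Cz, random phase per trial),
* a multiplicative ERD envelope on the rhythms during 3–7 s: amplitude
  ×(1 − erd_depth) on the contralateral electrode, ×(1 − erd_depth·(1 −
  lateralization)) ipsilaterally, with 0.25 s raised-cosine ramps; Cz is
  class-independent.

Subjects differ by seeded draws: mu centre 9–13 Hz, beta centre 18–24 Hz,
erd_depth 0.45–0.75, lateralization 0.6–1.0, noise_sd 0.8–1.2. These
ranges are package choices — chosen once to give a clearly decodable but
not trivial signal (a logistic rule on the C3−C4 mu-power difference
reaches >0.7 accuracy from erd_depth 0.4) — since no quantitative subject
characterization is available to copy. The generator omits ocular/muscular
artifacts, electrode drift, and cross-session nonstationarity; passing
tests therefore demonstrate that the pipeline's machinery is correct and
that transfer helps *when subjects genuinely share ERD structure*, not that
the same margins would be obtained on real recordings.

## Scaled-down experiments

The packaged comparison (`experiments.itsd_vs_sd`) uses 9 subjects × 90
trials, 3-fold CV, the target's per-fold training capped at 60 trials, a
transfer cap of 25 instances per source subject, and 12 training epochs at
learning rate 0.02 — sizes chosen so a full 5-seed comparison completes in
a few minutes on one core while keeping the defining features of the
protocol (data-starved target, 8 source subjects, leakage-free per-fold
transfer). The paper-scale optimizer default (lr 1e−4, 6 epochs, batch 50)
is kept as the `CnnConfig` default for full-scale runs; at desk scale it
would leave the network near its initialization, so the experiments state
their own rate. The label-permutation negative control uses 240 trials and
2 epochs: with labels shuffled there is nothing to learn, and pooled
held-out accuracy lands at 0.5 within binomial noise.

## Numerical and degenerate-input choices

* DCT is `scipy.fft.dctn(norm="ortho")`; a brute-force O(N⁴) double sum is
  the test oracle.
* Hash tie-break: coefficient exactly equal to the threshold mean → bit 0.
* Min–max of a constant matrix → zeros (no NaN for any finite input).
* Softmax ties → lower class index (numpy argmax).
* `StftSpec` columns use only windows fully inside the epoch (no padding).
* One master seed derives all stage seeds via `numpy.random.SeedSequence`;
  every derived seed is kept below 2³¹.

## Known limitations

* Real recordings enter either as a conforming HDF5 container
  (`read_container`) or through `container.trials_from_mne_raw`, which cuts
  cue-locked trials from any MNE `Raw` object (hence EDF/GDF via
  `mne.io.read_raw_*`). The adapter is unit-tested on synthetic `RawArray`
  data only; it has not been exercised against real benchmark recordings.
* The NumPy CNN is single-threaded and CPU-bound; at the full protocol
  scale (648 training trials × 10 folds × 9 subjects) a run takes hours,
  which is why the packaged experiments are scaled down.
* Hash distances between normalized EEG spectrograms are small (typically
  0–6 bits of 64): the images share most of their coarse structure, so the
  code discriminates on fine class/subject differences only. The ordering
  (same class closer than different class) is what the transfer mechanism
  uses, and is property-tested.
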