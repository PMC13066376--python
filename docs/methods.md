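# Methods

`meetsemg` implements a surface-electromyography (sEMG) hand-gesture
recognition pipeline built around a class-partitioned mixture of experts of
extremely randomized trees ("MEET"). This note records the models, the
defaults and why they were chosen, the numerical conventions, and the known
limits of what the synthetic data can demonstrate.

## The classifier

Let the gesture classes be the ascending codes `1..N` and let `a` be the
number of classes assigned to each expert (default `a = 2`). The classes
are split into consecutive ascending subsets of size `a` (the last subset
may be smaller), giving `ceil(N/a)` experts; one additional *gate*
classifier is trained on all classes, for a total of

    n_classifiers = ceil(N / a) + 1.

Every classifier is an `ExtraTreesClassifier` with 100 trees, Gini
impurity, `min_samples_split = 2`, `min_samples_leaf = 1` and `sqrt`
feature subsampling. Expert *i* is fitted only on the training rows whose
label falls in subset *i*; the gate sees all rows. For a feature vector
the experts' class-probability outputs are stacked into a length-`N`
vector `Z` aligned with the ascending class order — each class is owned by
exactly one expert, so within each expert's block `Z` sums to 1 — and the
gate emits its length-`N` probability vector `M`. The prediction is

    y = argmax( Z ⊙ M )

(elementwise product), ties broken toward the lowest class code. With a
uniform gate this reduces to the argmax of the stacked expert outputs.
The stacking-by-class semantics is the normative fusion; an alternative
mode (`fusion="per_expert"`) that pools the gate's probability mass per
expert before weighting that expert's block is available for comparison.

Seeding: the master seed is fanned out through `numpy.random.SeedSequence`
keyed by each expert's class subset, so experts can be trained
independently (serially or in parallel) with identical results, and an
expert's fit does not depend on the presence of other classes' rows.

Since a constant classifier on balanced `N`-class data scores exactly
`1/N`, that value is the bias floor against which the ensemble is tested.

## Signal path

1. **Bandpass** 10–500 Hz, 4th-order Butterworth (the quartic overall
   order is realised as `scipy.signal.butter(order // 2, btype="bandpass")`),
   applied forward-backward (`sosfiltfilt`) for zero phase so labels and
   features stay aligned. Zero-phase application squares the magnitude
   response; the passband `[2·low, high/1.5]` stays within 1 dB of the
   configured gain and 2 Hz content is attenuated by more than 20 dB.
   Whether a causal or zero-phase filter is used does not change any
   windowed feature materially for stationary bursts; zero-phase was
   chosen to avoid group-delay misalignment.
2. **Notch** at 50 Hz, second-order IIR (`iirnotch`), quality factor 30,
   zero phase. Q = 30 keeps the −1 dB impact radius well inside ±20 Hz.
3. **Windowing**: 256 ms windows with 25 % overlap. With
   `W = round(window_ms·fs/1000)` and step `S = round(W·(1−overlap))`,
   window *i* covers samples `[i·S, i·S + W)` (0-based, half-open);
   trailing samples are dropped. At 2000 Hz: `W = 512`, `S = 384`,
   consecutive windows share 128 samples, and a 480,000-sample recording
   yields `⌊(480000−512)/384⌋ + 1 = 1249` windows. A window's label is
   the majority of its per-sample labels, ties toward the lower code
   (ties only arise at synthetic block boundaries).

## Features

17 per channel and window — 11 time-domain (MAV, VAR, DASDV, WL, IEMG,
LOG, RMS, AAC, ZC, WAMP, MYOP) and 6 frequency-domain (TTP, FR, MDF, PKF,
MNF, MNP); the exact formulas are in the `meetsemg.features` module
docstring and are the normative definitions for this package. Choices
worth calling out:

- **VAR** is computed about the window mean with denominator `W − 1`.
  Some EMG texts assume a zero-mean signal and divide `Σx²` by `W − 1`;
  after the bandpass the signal is near zero-mean, so the difference is
  negligible, but the mean-centred form is the documented one.
- **Thresholds** (absolute, on the millivolt-scale signal): zero-crossing
  0, Willison amplitude 0.01, myopulse 0.016. They are exposed in
  `FeatureParams`; the literature states no canonical values.
- **Spectrum**: one-sided periodogram, rectangular window, `"spectrum"`
  scaling with detrending disabled, so that `ΣP_j = mean(x²)` exactly
  (Parseval); TTP is therefore the mean power of the raw window. Welch
  averaging is available via `psd_method="welch"`.
- **FR** splits the band at 250 Hz (midpoint of the 10–500 Hz EMG band).
  A bin lying on the split (to 1e-9 relative) counts as low band. A
  window with no high-band power (e.g. all zeros) gets the sentinel
  FR = 0 with a warning.

## Synthetic acquisition

No public recording accompanies the acquisition protocol, so the
generator emulates it statistically: per subject, `n_classes = 6` gesture
blocks of 40 s each at 2000 Hz on 2 channels (480,000 samples per
subject; 1,920,000 over the default 4 subjects). Within a block the
gesture is repeated continuously: repetition cycles are drawn uniformly
from 1–2 s, the muscle is active for 70 % of each cycle with 50 ms
raised-cosine on/off ramps, and between repetitions activation falls to a
residual `rest_floor` (default 0.15 of the burst amplitude) rather than
zero — the task is held continuously, so full relaxation between efforts
would be unphysiological, and it would leave rest-only windows with a
class label but no class information.

Each class has a signature: burst amplitude (0.8–1.3 mV RMS across the
six defaults), spectral center (evenly spread 80–400 Hz) and −3 dB
bandwidth (60 Hz). Bursts are Gaussian noise shaped by a single-peaked
resonator (`iirpeak`) whose maximum sits exactly at the configured
center; real sEMG spectra are likewise unimodal, and a unique spectral
maximum makes the configured center recoverable from an averaged
periodogram (to within one Welch bin at high SNR). Contamination:
50 Hz powerline (0.10 mV), sub-5 Hz baseline drift (0.05 mV at 0.5 Hz),
and white sensor noise (sd 0.02 mV). All draws come from one seeded
generator; a fixed seed reproduces the recording byte for byte.

What the generator does *not* emulate: motor-unit action-potential
trains and recruitment, amplitude non-stationarity within a burst,
fatigue across the 40 s block, electrode-shift artifacts, and
cross-subject variability beyond the random seed. Classes are separable
by construction (distinct amplitudes and spectral centers), so a high
synthetic accuracy demonstrates that the pipeline recovers a known
structure — not that comparable accuracy would be reached on recorded
muscle data.

Rest labelling is configurable: by default inter-repetition rest keeps
the block's class label (the whole block is windowed, matching the
blocked protocol); `label_rest_as_block=False` labels rest samples 0
instead, for experiments that discard rest before windowing.

## Evaluation

The confusion matrix is stored rows = actual, columns = predicted.
Accuracy is trace/total; per-class precision, recall and F1 come from the
one-vs-rest Tp/Fp/Tn/Fn counts, and summary values are unweighted (macro)
class means by default, with support-weighted averaging behind a flag. A
class never predicted gets precision 0 with a logged warning. Model
comparisons share one class-stratified 70/30 split at a recorded seed.
Per-subject accuracies of two models are compared with a paired,
two-tailed Student t-test (`d = a − b`, `t = mean(d)/(sd(d)/√n)`, sample
sd, `n − 1` degrees of freedom); zero-variance differences are rejected
as degenerate rather than reported as infinite.

Applied to the published per-subject accuracies of the proposed model
(86.80, 89.20, 87.90, 78.40 %) against its Extra-Trees baseline (85.20,
87.30, 87.15, 76.60 %), this procedure gives t = 5.7794, p = 0.0103, and
the four-subject mean is 85.575 % — the values `scripts/acceptance.py`
recomputes.

## Problem sizes and determinism

Unit tests run on shortened protocols (2–8 s gesture blocks); the
acceptance script and the class-recovery check use a full 40 s × 6-gesture
subject (1249 windows, 34 features). One master seed drives generation,
splitting and training end to end; `run_experiment` re-run with the same
config writes identical metrics JSON (timestamps aside).

## Known limitations

- The per-subject accuracies of the original four-subject recordings are
  not reproducible here: that data is private, and synthetic accuracy
  depends on the configured class separability rather than physiology.
- The gate and experts are fused without probability calibration; with
  100-tree ensembles the uncalibrated probabilities are already smooth,
  but fusion behaviour under heavily imbalanced training data is
  untested.
- Only the uniform-`a` consecutive partition is normative; data-driven
  partitions (e.g. grouping confusable gestures) are out of scope.
- Streaming/real-time filtering is not supported; filters are zero-phase
  and therefore acausal.
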