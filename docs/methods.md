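# Methods

This note records the model, the choices that were genuinely open, and what
the synthetic experiments do and do not establish.

## Pipeline

1. **Segmentation.** Recordings are cut into 5 s windows.  Nonseizure
   windows tile seizure-free stretches with no overlap; seizure windows
   slide inside annotated intervals with a configurable overlap fraction
   (default 0.5), reflecting that seizure data is scarce and must be
   oversampled to reach the target segment count.  A window is labeled only
   if it lies entirely inside or entirely outside the annotated intervals;
   straddling windows are discarded.  Boundary handling is our choice — the
   clean two-class protocol leaves onset/offset windows undefined, and
   discarding them avoids training on mixed content.
2. **Features.** Each window yields an N×N cross-power matrix: the Welch
   cross-spectral density (1 s Hann subwindows, 50% overlap — standard for
   5 s windows at 256 Hz) integrated (trapezoid) over the selected band.
   The CSD is complex; we integrate its magnitude, which yields the real,
   symmetric, nonnegative matrix the rest of the pipeline assumes.  A
   real-part mode is available (`csd_mode="real"`), but magnitude is the
   default because band-integrated |P_ij| of two coherent channels equals
   their diagonal power regardless of relative phase, which is the
   synchronization signature of interest.  The full N² vector is kept
   (not the upper triangle) so the input layer matches the squared channel
   count exactly.
3. **Band selection.** Fisher's discriminant ratio is applied once per
   candidate band to the *pooled* scalar set of all matrix entries of all
   training segments per class.  Pooling matches the scalar form of the
   ratio; a per-entry-then-average mode exists behind a flag.  Only the
   training split is ever passed to band selection or scaler fitting (a
   test audits this).
4. **Scaling.** Raw band powers span orders of magnitude (an EMG burst can
   put a cross-power entry at ~10⁴ against a baseline of ~10²), which no
   sigmoid decoder can reconstruct and which would make a fixed kernel size
   meaningless.  Features are mapped by log(1+x) followed by a train-set
   min–max to [0, 1] with clipping; constant features scale to 0.  The
   σ = 0.05 default kernel size is interpreted on this unit scale.
5. **Network.** Sigmoid autoencoders pretrained layer-wise
   ([N², 50, q], q = 10 default), encoder halves stacked, 2-class softmax
   head, joint fine-tuning of all parameters on cross-entropy plus weight
   decay.  Sparsity is a pretraining device only and is not applied during
   fine-tuning, matching common stacked-autoencoder practice.  Predicted
   ties go to nonseizure (conservative alarm policy).

## Losses

Both costs share KL sparsity (β = 3, ρ = 0.1) and weight decay (λ = 0.003).
The robust cost replaces the mean-square reconstruction term with negated
sample correntropy, J_MCC = (1/n) Σᵢ Σⱼ κ_σ(x_ij − y_ij).  Properties the
tests pin down:

* **Bounded influence.** One arbitrarily corrupted entry changes J_MCC by
  at most κ_σ(0)/n; the same perturbation changes J_MSE without bound.
* **Large-σ equivalence.** For errors ≪ σ, κ_σ is quadratic to second
  order, so rankings by −J_MCC and J_MSE coincide; σ controls where the
  loss transitions from quadratic to saturated.

**Kernel normalization.** The Gaussian kernel's 1/(√(2π)σ) factor is kept
in the standalone kernel/correntropy functions (their closed-form values
follow the textbook definition) but dropped from the *training* cost by
default (`AEConfig.kernel_normalized`).  Inside the regularized cost the
factor multiplies only the reconstruction term — ×7.98 at σ = 0.05 —
silently weakening the shared β and λ roughly eightfold relative to the
MSE cost and making the regularization balance depend on σ across a kernel
sweep.  Dropping it keeps the published parameter set meaningful for both
losses and leaves the optima of the unregularized loss unchanged.  Measured
effect: mean hidden activation after pretraining is 0.13 (unnormalized)
vs 0.20 (normalized) against the ρ = 0.1 target.

## Optimization

The optimizer is full-batch L-BFGS with analytic gradients (verified against
central finite differences to ≤10⁻⁶ relative error), up to 400 iterations
per stage, gradient tolerance 10⁻⁶; runs are deterministic given the seed,
which controls only the symmetric uniform ±√(6/(fan_in+fan_out))
initialization.  A quasi-Newton full-batch method was preferred over
stochastic descent for exact reproducibility.

**Kernel-size continuation.** The correntropy objective at σ = 0.05 is
severely non-convex: any entry whose error exceeds a few σ contributes
near-zero gradient, so a cold start fits only what it already almost
reconstructs.  Training therefore anneals σ from 0.8 by halving (each warm
stage capped at max_iter/8 iterations) and finishes with a full-length stage
at the target σ — the objective finally minimized is exactly the
target-kernel cost.  Continuation of the kernel size is the standard remedy
for correntropy objectives; without it the robust autoencoder reconstructs
*worse* than the MSE one.

Numerical guards: mean activations are clamped to [10⁻⁸, 1−10⁻⁸] before the
KL term (saturated units would otherwise produce infinities; the clamp's
gradient is zero where active); non-finite costs abort training with an
error rather than silently producing NaN parameters.

## Synthetic data

The generator produces the statistical structure the pipeline consumes,
not physiological EEG:

* **Background**: per-channel pink (1/f-shaped, 1 Hz floor) noise at
  20 µV RMS plus a 20% common-mode component so baseline cross-power is
  nonzero.
* **Seizure**: a sinusoid with slowly drifting frequency confined to the
  configured band (default alpha, 8–13 Hz) at 30 µV RMS, added with
  near-identical phase (0.05 rad jitter) to 75% of the channels — the
  excessive cross-channel synchronization that marks ictal EEG.
* **Artifacts**: Poisson bursts (default 3/min, 0.3 s, 20× background
  amplitude) of 15 Hz-high-passed noise, one source waveform coupled into
  1–3 channels so burst cross-power is coherent — the impulsive outlier
  regime.  Bursts are injected into both classes at the same rate, so they
  carry no label information; a classifier exploiting bursts alone performs
  at chance.

Defaults (8 channels, 256 Hz, 1000 seizure + 4000 nonseizure segments,
750 + 750 training) mirror the segment-count protocol of clinical studies
at a desk-scale channel count.  Amplitudes were fixed once at values giving
clearly separated but artifact-contaminated classes.  Under these
conditions detection is nearly perfect (sensitivity/specificity ≈ 1.0);
passing tests therefore demonstrate that the pipeline recovers strong
synchronization structure under impulsive noise, *not* clinical-grade
performance: real seizure morphology is diverse and nonstationary, real
artifacts are heterogeneous, and real class boundaries (onset/offset) are
ambiguous in ways the generator does not model.

## Experiment protocol

An experiment fixes one dataset and one train/test split, then repeats
training over n_trials (default 10) varying only initialization seeds
(derived from the master seed by seed-sequence hashing), reporting
mean ± std.  R-SAE/S-SAE comparisons are paired: identical split, band,
scaler and per-trial initialization; only the loss differs.  "Before
fine-tuning" metrics train the softmax head on frozen pretrained features;
fine-tuning then starts from that model.  Metrics are segment-level;
event-level alarm logic is out of scope.

## Known limitations

* The sliding-window seizure oversampling makes seizure segments
  correlated; per-segment metrics on synthetic data are optimistic in the
  same way the fixed-split clinical protocol is.
* Band selection considers only the three canonical bands; a custom band is
  accepted but not searched automatically.
* The optimizer is full-batch; inputs far larger than ~10⁴ segments ×
  784 features would need minibatching, which is deliberately unsupported.
* EDF reading assumes a uniform sampling rate across channels.
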