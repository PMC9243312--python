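# Methods

## Problem and model

`eegauth` implements an EEG identity-authentication framework for oddball
name tasks: a subject views their own name (rare, *genuine*) among
familiar and stranger names (frequent, *impostor*) plus blank screens.
The evoked response carries three identity-bearing event-related
potential (ERP) components — P200 (~200 ms, positive), P300 (~300-600 ms,
positive, the dominant low-frequency response with energy centered at
375-625 ms and below 10 Hz) and a late negativity (LN, ~650 ms) — whose
amplitudes, latencies and frontal/central topographies differ between
self and non-self stimuli and between subjects.  Authentication is a
per-subject binary classification: self trials versus familiar+stranger
trials.

Each clean trial is converted to a **spatial-temporal-frequency tensor**:
per channel, a Hamming-windowed short-time power spectrogram (window 64
samples, hop 7, 256-point FFT at 256 Hz) of the 0-800 ms post-stimulus
segment, restricted to 0-30 Hz and resampled onto a canonical 94 (time) x
60 (frequency) pixel grid; stacking 16 channels gives a 16 x 94 x 60
tensor.  One canonical pixel spans 800/94 ms x 0.5 Hz; kernel extents in
physical units are quoted with the rounded pixel scale (8.5 ms, 0.5 Hz),
so a 3 x 3 kernel covers 25.5 ms x 1.5 Hz.  Note the stated spectrogram
parameters alone yield ~21 frames x 1 Hz bins from a 205-sample segment;
the canonical grid is reached by separable linear interpolation
(edge-held outside the frame-center span), which preserves the tensor
contract, non-negativity, constants, and the quadratic scaling of power.

The classifier family consists of **multi-scale vision convolution
networks**: stacks of 3-5 modules, each with an optional 1x1
channel-reduction convolution, parallel branches convolving the shared
input with kernels of different scales (batch-normalized, leaky-ReLU
alpha = 0.01), channel concatenation, and max pooling whose kernel area
shrinks with depth.  Branch paddings follow `pad = (k - k_min)/2` per
axis so branch outputs align for concatenation.  The head is dropout
0.4 -> linear -> leaky ReLU -> dropout 0.4 -> linear(32 -> 2) -> softmax;
the first linear layer's input size is the computed flatten size.
Weights are kaiming-uniform (bound sqrt(6/fan_in)), biases zero.  Ten
reference architectures ship as YAML (1D/2D/3D x serial single-scale and
multi-scale long/wide/equal variants); 3D kernels are quoted spatial x
temporal x frequency with a fixed spatial depth of 6 and no spatial
padding.  Training uses softmax cross-entropy (the head defines it
implicitly) with Adam at learning rate 5 x 10^-4, 5 epochs, batch 50 by
default; SGD is selectable.  Class imbalance (100 genuine vs 450
impostor trials in a default session) is handled by balanced mini-batch
sampling, and balanced accuracy is reported alongside plain accuracy.

The networks run on a compact numpy engine written for this package
(`eegauth._nn`): stride-1 N-dimensional convolution as chunked im2col
GEMMs (float32, ~64 MB im2col budget), exact gradients (verified against
numeric differentiation in the test suite), batch-norm, non-overlapping
max pooling, inverted dropout, and Adam/SGD.  Determinism: every
stochastic element (weight init, dropout, batch sampling, the synthetic
generator) derives from explicit integer seeds.

## Preprocessing chain

Fixed order: zero-phase band-pass -> resample to 256 Hz -> re-reference ->
epoch (-200..800 ms) + baseline (-200..0 ms mean removal) -> ICA ocular
removal (optional) -> >100 uV amplitude rejection -> blank-average
subtraction.  `run_pipeline` records the realized order.

* Band-pass: order-2 Chebyshev type-I sections designed from the
  passband spec (low-pass edge 20 Hz / 0.5 dB ripple; high-pass edge
  0.5 Hz / 0.5 dB) and *verified* post hoc against the stopband
  requirements (>= 5 dB at 40 Hz, >= 10 dB at 0.01 Hz); an unmeetable
  spec raises.  The type is over-determined by quoting both ripple and
  stopband attenuation at order 2; designing type I from the passband
  and checking the stopband is the testable resolution.  Filtering is
  forward-backward (zero phase) because ERP latency is an identity
  feature; this doubles each section's passband deviation, so a sinusoid
  through the full cascade is preserved within 2 dB, while the designed
  single-pass response stays within the 0.5 dB ripple.
* Re-referencing defaults to the common average (idempotent; channel
  mean exactly zero).  Reference-electrode standardization (REST) needs
  a head-model lead field the package cannot supply; `rereference(...,
  "rest", lead_field=G)` accepts a user matrix.
* Ocular removal: FastICA on trial-concatenated data; components whose
  time course correlates with an EOG proxy (default: mean of Fp1/Fp2)
  above |r| >= 0.6 are zeroed before back-projection.  Decomposition
  failures propagate.
* Rejection applies to post-filter, pre-subtraction epochs; all-trials
  rejected is an explicit error.
* The blank (no-text) grand average is subtracted from every name trial;
  in cohort evaluation it is computed from training subjects only to
  avoid leakage (the evaluation protocol's choice, recorded in the run
  config).

## Synthetic cohort generator

No public dataset accompanies the task, so the generator *is* the study
population for every experiment here.  Each component is a
Gaussian-windowed half-cosine bump (3 parameters: latency, amplitude,
width; smooth and band-limited), multiplied by a frontal/central
topography peaking at Fz/F3/F4/C3/C4 (unit max-abs).  Per-subject
parameters are drawn once from a subject seed (latency, amplitude,
width, topography jitter), making subjects distinct but reproducible;
per-trial jitter (latency sd 8/18/12 ms, amplitude sd 0.4/0.6/0.4 uV for
P200/P300/LN) is drawn from trial seeds.  The seed hierarchy master ->
subject -> trial makes a cohort a pure function of its spec.

Defaults emulate the stated session: 16 channels at 256 Hz, epochs
-200..800 ms, 100 self / 150 familiar / 300 stranger / 50 blank trials,
ERP amplitudes below 10 uV (P200 ~3.5, P300 ~3.8, LN ~-2.6 uV base),
P300 latency ~460 ms (clipped to [250, 650]), background noise 10 uV RMS
with a steep low-frequency spectrum (power ~ 1/f^2, >90% of power below
30 Hz, matching the task's low-frequency character), optional 50 Hz line
interference and optional >100 uV frontal ocular transients to exercise
rejection.  The oddball identity effect scales with a single margin
parameter m (default 0.5): self P300 amplitude = (1 + m) x non-self
(the 1.5x default), latency earlier by 40m ms, with weaker co-modulation
of P200 and LN (factor 0.5m) so that all three components carry class
information at their own temporal scales; familiar names sit 20% of the
way from stranger to self.  Margin 0 collapses the name classes exactly.
A matched-filter statistic on noise-free templates provides the
independent separability oracle for the margin-monotonicity property.

What the generator does **not** emulate: volume-conducted correlated
noise, non-stationarity across a session, realistic eye-movement
kinematics, or the single-trial variability structure of real EEG.
Passing tests therefore demonstrate the pipeline's correctness and the
direction of architectural effects on data with the assumed statistical
structure — not performance on real recordings.

## Desk-scale experiment conditions

The comparative designs (16-kernel sweep, strategy comparison, branch x
depth grid) run at desk scale on one CPU core: small cohorts
(30-60 trials per class per subject), reduced channel widths (4-16 per
branch versus the reference 24/72), two-fold or holdout evaluation, a
short optimization schedule (Adam, learning rate 2 x 10^-3, batch 12,
25-80 iterations), and background noise 2.5 uV RMS.  The lower noise is
deliberate: at a few dozen trials the jitter-induced class overlap
already bounds accuracy, and the reference noise level pushes all desk
networks toward chance, hiding architecture effects; 2.5 uV keeps
within-subject accuracy in the ~0.65-0.85 range where orderings are
measurable.  Reference-scale settings (70 subjects, full trial counts,
the printed widths, learning rate 5 x 10^-4 / 5 epochs / batch 50,
100 cohort rounds) remain plain config values.  Networks are trained on
log-power (`log1p`) inputs standardized per feature with
training-split statistics; both transforms are classifier options
recorded in its parameters.

All comparative claims are evaluated *directionally* over >= 5 seeds
(mean ranks or means, never point equalities): long kernels outrank wide
ones; the 3-branch multi-scale net beats the serial large-kernel
single-scale net; the branch-count gain concentrates at 2 -> 3 (matching
the three ERP components); training loss at iteration 3000 sits below
iteration 100.  Effect sizes at desk scale are not transferable to the
reference data and are not asserted.

## Evaluation protocols

* **Within-subject CV**: stratified 5-fold on one subject's trials;
  every trial tested exactly once; feature standardization from fold
  training data only.
* **Cohort rounds**: repeated random disjoint splits of subjects into
  training (fixes architecture, hyperparameters, blank average and any
  normalization) and test groups; each test subject is scored with a
  stratified within-subject holdout (default 20%) under the fixed
  configuration; rounds are averaged.  How the reference protocol
  combined the subject split with per-subject evaluation is not fully
  specified; both protocols are first-class here and reported
  separately, with no claim that either equals the published pooling.

## Numerical choices and degenerate inputs

* Spectrogram values are raw windowed-DFT power (no window
  normalization, no one-sided doubling), making the brute-force DFT
  oracle an exact dual route (tolerance 1e-6 relative).
* Frequency pixels center at 0.25, 0.75, ..., 29.75 Hz (60 half-Hz bins
  spanning 0-30 Hz, avoiding a fencepost 61st bin); time pixels center
  at (i + 1/2) * 800/94 ms.
* A constant feature map z-scores to all zeros with a warning (sd = 0
  guard).  Padding parity mismatches, pooling that exhausts an axis, and
  kernels larger than their padded input raise constructive errors
  naming the offending module.
* Epoch markers without full -200/+800 ms context are dropped with a
  warning; an all-rejected amplitude screen is an error, never silent.
* The kernel-extent table reproduces the published physical-extent
  arithmetic and *flags* printed cells that disagree with the pixel
  scale (several 7/9-pixel frequency extents print 5.5 Hz where the
  0.5 Hz/pixel arithmetic gives 3.5/4.5 Hz); the flags are data, not
  corrections.

## Known limitations

* The numpy engine targets correctness and desk-scale sizes; full-size
  3D multi-scale training is outside its practical envelope (the
  architecture suite is still built and gradient-checked at full input
  size).
* REST re-referencing is only available with a user-supplied lead
  field; the default is the common average.
* ICA component selection is a single EOG-correlation criterion; no
  automatic artifact taxonomy.
* Biometric metrics beyond (balanced) accuracy — EER, ROC — are out of
  scope.
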