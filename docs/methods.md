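# Methods

## Problem setting

A forearm EMG armband records 8 channels at a nominal 1,000 Hz while a
user performs cued, ~1 s static holds of hand gestures; a hand-tracking
stream supplies frame timestamps at ~72 Hz on average. The task is
gesture classification that survives *session changes*: every re-donning
of the armband shifts electrode positions, contact impedances and noise
conditions, so a classifier trained on earlier sessions degrades on a
new one. The package implements and compares three training schemes —
single-session, cumulative (pooled), and session-recalibration — and
ships a synthetic multi-session generator so the whole pipeline runs and
is testable without any recording hardware.

## Signal pipeline

1. **Scaling.** Raw ADC counts are converted to millivolts with a linear
   gain (V/count), taken from session metadata.
2. **Filtering.** 4th-order Butterworth band-pass 60–500 Hz (motion
   artifacts) plus two second-order IIR notches at 60 and 120 Hz
   (power-line interference), Q = 30. All filters are applied
   forward–backward (zero phase, reflect padding) so samples never shift
   against the annotation timeline. The filter family and order are our
   choice; the band edges and notch frequencies are fixed by the
   protocol.
3. **Downsampling.** A zero-phase 4th-order Butterworth low-pass at
   30 Hz guards against aliasing (the 72 Hz target has a ~36 Hz
   Nyquist), then the EMG sample nearest each kinematic timestamp is
   kept, so every kinematic frame has exactly one EMG column.
   Deliberately, the band-pass runs *before* the anti-alias low-pass, in
   the pipeline's stated order; the surviving content is the small
   spectral overlap of the two designs plus aliased residual. What
   remains is noise-like within a window, and the class information
   lives almost entirely in the per-channel amplitude (covariance)
   structure — both for the simulator and, we expect, for real
   recordings processed the same way.

Classifier samples are 8×24 windows of the processed series (24
kinematic frames ≈ 330 ms), slid at a configurable stride entirely
inside one annotated hold.

## Leakage-free splitting

Overlapping windows make random window-level splits leak near-duplicate
data across train/test. All splits therefore assign whole *gesture
instances*: an 80/20 split of 10 instances per class puts the first
eight instances of each class in training. Because idle gaps between
instances always exceed the window duration, windows from different
instances share no raw sample; the test suite verifies this by
exhaustive index-set intersection. Instance-based k-fold
cross-validation (5-fold, two repeats, seeded shuffling) is available
for single-session evaluation; the bundled multi-seed study averages
over seeds instead of folds to keep its CPU footprint proportionate
(each seed already regenerates data, templates and initializations).

## Models

**Backbone** (session-agnostic classifier, shaped like a symmetric
autoencoder without a reconstruction loss):

- encoder: BiLSTM(8→H) → BiLSTM(2H→H) → FC(2H→F, leaky ReLU) →
  FC(F→4, tanh) = **bottleneck** (4 units);
- decoder (mirror): FC(4→F) → FC(F→2H) → the result repeated across the
  24 time steps → BiLSTM(2H→H) → BiLSTM(2H→H);
- head: softmax over the gesture classes on the concatenated final
  recurrent states.

The two fully-connected layer counts and the 4-unit bottleneck are fixed
by the architecture; the widths are ours. Full-size defaults are H = 64
per direction, F = 32, dropout 0.25 between layers; the bundled
synthetic study uses a CPU-scale variant (below).

**Session calibrator**: a residual time-distributed channel mixer,
`y_t = x_t + W2·leaky(W1·x_t + b1) + b2`, shared across the 24 steps, so
the window shape (8×24) is preserved. The residual form anchors the map
to the identity: armband re-donning effects (gain, offset, rotation,
placement change) are near-identity channel maps, and a partially
trained calibrator can never collapse the signal — important because the
first calibrator phase runs against a still-untrained backbone.
Identity initialization zeroes the output layer (exact pass-through).

**Numerics.** Both networks are implemented directly on float32 numpy
arrays with hand-written reverse-mode gradients; the LSTM time loops are
numba-compiled with a branchless all-float32 rational (Padé 7,6) tanh on
a clamped argument — the clamp saturates just below 1, so saturated
gates keep a nonzero gradient factor (forward error vs. exact tanh
< 10⁻³, checked against a float64 reference). Correctness is pinned by
a finite-difference directional-derivative test. Inputs are standardized by one scalar gain (fit on
training windows, target SD ≈ 3) applied *before* the calibrator, so
both networks operate at unit signal scale — Adam's absolute step size
would otherwise dwarf millivolt-scale inputs. Adam (β₁ = 0.9,
β₂ = 0.999) with global gradient-norm clipping at 5; early stopping on
validation loss (restore best). Frozen models are skipped entirely by
the optimizer, so freezing is bitwise exact.

## Training schemes

- **Single-session**: 70/10/20 instance split of one session.
- **Cumulative**: first 80% of instances of every training session
  pooled for training, the last 20% of each for validation; held-out
  sessions are scored on all their windows with no adaptation.
- **Recalibration**: sessions are visited chronologically; per session a
  fresh identity-initialized calibrator is trained with the backbone
  frozen, then the backbone is trained with the calibrator frozen (both
  on that session's 80/20 split). On an unseen session the same two
  stages run on the first 20% of instances (the next 20% drives early
  stopping), and accuracy is measured on the final 60%, which the model
  never saw. The trained backbone itself is not mutated at test time —
  the second stage fine-tunes a per-session clone.

Calibrator phases use a hotter learning rate (0.01) than backbone phases
— the calibrator is a tiny shallow network — and test-time
recalibration allows a larger epoch budget (default cap 40) on its
small calibration set, since each epoch there is only a few batches.
Running the backbone stage at test time as well follows the scheme's
two-stage description of what happens "whenever a new session is
introduced"; a calibrator-only variant is available via
`TrainConfig(adapt_backbone_at_test=False)`.

## Synthetic data generator

Channel model:
`x_c(t) = g_c · Σ_m W'[c,m] · envelope_m(t) · carrier_m(t) + offset_c + line(t) + noise(t)`.

- **Templates**: each gesture recruits about half of the muscle groups
  with random strengths (unit-norm amplitude vectors, pairwise distance
  ≥ 0.5); envelopes are raised-cosine-edged ~1 s bumps, zero in the idle
  gaps. One template set is shared by all sessions of a dataset.
- **Carriers**: band-limited (60–500 Hz) unit-variance Gaussian noise
  per muscle — a stand-in for the asynchronous interference pattern of
  many motor units; no motor-unit recruitment model is attempted.
- **Session perturbation**: per-channel gains, fractional circular
  electrode rotation (linear interpolation of the mixing-matrix rows),
  additive mixing-matrix jitter (electrode placement change beyond pure
  rotation: tilt, translation, contact quality), baseline offsets,
  sensor noise, and 60 Hz line interference. Severity levels ("none",
  "mild", "moderate", "severe") scale all components monotonically;
  "moderate" draws gains in [0.7, 1.3] and ~1-channel rotations.
- Instances appear in randomized order with jittered idle gaps that
  always exceed the window duration; kinematic timestamps are jittered
  around the 72 Hz mean; EMG is emitted as integer ADC counts
  (0.1 µV/count).

The mixing-jitter component earns a note: with gain + rotation alone,
inter-session variation spans a low-dimensional family that a pooled
model trained on twelve sessions marginalizes almost completely, and
per-session recalibration then has nothing to add — unlike what is
observed on real multi-session recordings. Placement jitter is
higher-dimensional: pooling cannot average it away, but it is still an
(invertible) linear channel map, exactly the class of distortion a
per-session calibrator can undo. Its moderate scale (SD 0.20 on mixing
weights of order 1) was set so that the generator actually produces the
domain-shift regime it exists to model — a pooled model loses ≥ 10
accuracy points relative to the no-shift condition, single-session and
pooled training land close together, and rapid recalibration has
headroom to separate from both.

What the generator does *not* emulate: motor-unit firing statistics,
electrode-skin frequency-dependent impedance, within-session drift
(fatigue), behavioral variability of gesture execution, or kinematic
joint angles (timestamps only). Passing the bundled study therefore
shows that the pipeline mechanics and the scheme comparison behave as
designed under linear channel-map session shift — not that comparable
accuracies would be reached on any particular real recording.

At these small widths, a from-scratch backbone fit occasionally stalls
in a class-merge local minimum (training accuracy pinned at an exact
class-fraction plateau); `TrainConfig.n_restarts` trains several seeded
initializations and keeps the best by validation loss. The no-shift
consistency study uses two restarts for its from-scratch fits so the
pooled baseline reliably reaches its ceiling; the perturbed study uses
single fits for all schemes uniformly.

## The bundled desk-scale study

Dataset: 12 training + 3 test sessions, 6 gestures × 10 instances each,
moderate severity, five seeds (each seed regenerates templates,
perturbations, signals and model initializations). Model/optimizer at
desk scale (`desk_scale_configs`): H = 32, F = 16, dropout 0 (this model
underfits rather than overfits at this data scale, and dropout's
multiplicative noise starves the 4-unit bottleneck), learning rate
3 × 10⁻³ (the full-size default of 10⁻² is tuned for wider layers and is
unstable at these widths), window stride 2 (consecutive windows still
overlap by 22 of 24 frames), at most 8 epochs per session with patience
3, batch 128. The no-shift consistency companion study uses a 6 + 2
session dataset: without domain shift the comparison needs fewer
sessions to stabilize. All three schemes are scored on the same
final 60% of instances of each test session.

Typical per-seed wall time is ~3 minutes on one CPU core; accuracies at
this budget are deliberately mid-range so the scheme *ordering*, not a
ceiling effect, is what the study measures.

## Numerical and degenerate-input choices

- Fractional instance counts in splits: round half up per class, then
  repair so every non-empty fraction receives at least one instance.
- Instances shorter than 24 processed frames yield zero windows
  (logged, not an error).
- Kinematic frames outside the EMG range are dropped with a warning and
  counted.
- Window duration is defined as exactly 24 kinematic frames; holds give
  ~72 frames at the jittered 72 Hz rate rather than any fixed count.
- Already-millivolt input to the scaling step is a warned no-op.
- Silhouette (Euclidean, per-point mean) quantifies latent class
  separability; it is undefined (error) for a single class.

## Known limitations

- The LSTM engine is CPU-oriented; there is no GPU path and no batching
  across sequences of unequal length.
- The calibrator corrects linear channel maps well; nonlinear or
  time-varying session effects would need a richer front end.
- Sequential recalibration training keeps the backbone's internal
  reference frame drifting toward the most recent session; accuracy on
  a new session therefore depends on the two-stage test-time adaptation
  actually converging on its small calibration set.
- The no-shift consistency of recalibration vs. cumulative training
  holds at the study's accuracy plateau; at very low training budgets
  both schemes are noisy and the comparison widens.
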