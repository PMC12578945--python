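# Methods

This note records the scientific model behind `gaitmotion`, the defaults
and conventions it fixes, and what the synthetic-data results do and do
not show about real recordings.

## Problem setting

The pipeline classifies 5-second multichannel windows into five
functional motions (walk forwards, walk backwards, turn left 90°, turn
right 90°, squat/pick-up).  The sensor montage is 8 surface-EMG channels
— tibialis anterior (TA), gastrocnemius medialis (GM) and lateralis
(GL), and soleus (SOL), bilaterally — digitized at 1000 Hz by a 12-bit
ADC (1.1 V reference), plus three 9-axis IMUs (accelerometer, gyroscope,
magnetometer) at 25 Hz on the left shank, right shank and right foot.
After upsampling the IMU streams ×40 by linear interpolation, a trial is
a 5000×35 matrix at 1000 Hz.

## Synthetic trial generator

The generator reproduces the *statistical structure* a classifier
exploits, not the biophysics:

* **EMG.**  Each channel is a mid-scale baseline (2048 counts) plus a
  Gaussian white noise floor plus band-limited noise bursts: white noise
  filtered to 20–150 Hz (inside the 0.2–400 Hz conditioning passband,
  so bursts survive filtering), modulated by Gaussian envelopes at
  class- and muscle-specific onsets, scaled to ≈420 counts per unit
  envelope, then clipped and rounded to the 12-bit range.  The
  activation schedule is an editable module constant: during gait the
  plantarflexors (SOL/GM/GL) burst once per stride at push-off and the
  TA in swing, with the left leg half a stride out of phase; walking
  backwards reverses the roles; turns load the outer leg (three bursts
  over a 3-s turn, inner-leg amplitude ×0.35); the squat opens with a
  large bilateral TA burst (dorsiflexion as the knees travel forwards)
  followed by sustained low-level plantarflexor activity.  The EMG burst
  deliberately *leads* the corresponding kinematic excursion.
* **IMU.**  Accelerations are in g with the vertical axis at +1 g in
  quiet standing; gyroscopes in deg/s; magnetometers in arbitrary
  normalized units.  Walking produces per-step vertical-acceleration
  peaks and stride-frequency oscillations (larger on the foot sensor);
  the anteroposterior axis carries the direction sign.  Turns produce a
  sustained yaw rate of ±30 deg/s for 3 s — positive for left turns
  (counterclockwise-positive convention) — whose integral (90°) drives a
  slow magnetometer heading ramp.  The squat is a dip–rise on the
  vertical axis, a single smooth anteroposterior bump, and a bipolar
  shank pitch-rate excursion.
* **Subjects and trials.**  Per-subject parameters are drawn once per
  subject: per-channel gains log-uniform in [0.5, 2.0], activation
  latency uniform in [−0.15, +0.15] s, cadence uniform in
  [0.8, 1.2] strides/s, kinematic amplitude log-uniform in [0.6, 1.6],
  EMG noise floor uniform in [5, 15] counts, IMU noise floor uniform in
  [0.02, 0.08] g.  Per-trial draws (stride phase, event onset, small
  amplitude/timing jitters) come from a trial plan shared by all
  channels of the trial so modalities stay mutually consistent.  All
  randomness derives from `numpy.random.SeedSequence([seed, stream_key])`
  with documented stream keys, making every output a pure function of
  its seed.

Because per-trial z-normalization removes absolute scale, subject
identity is expressed mainly through cadence, latency and
signal-to-noise ratio; this is what makes naive cross-subject transfer
degrade while ten calibration trials per class recover it.

**What the generator does not emulate:** motor-unit physiology,
electrode-skin impedance drift, motion artifacts, sensor bias/saturation,
cross-talk between muscles, or realistic rigid-body dynamics.  Passing
tests on synthetic data therefore demonstrate that the pipeline's
machinery (conditioning, architectures, protocols) behaves as specified,
not that the reported accuracy levels transfer to physiological
recordings.

## Conditioning chain

EMG: ADC-to-volts (V = vref/(2^bits−1)·S), Hampel, band-pass
0.2–400 Hz, z-normalize.  IMU: band-pass 0.2–10 Hz, z-normalize.
Choices worth recording:

* **Hampel scale.**  "Three standard deviations from the 50 surrounding
  samples" is implemented with the robust scale 1.4826×MAD (the standard
  Hampel estimator); a plain windowed-std variant is available via
  `FilterConfig(hampel_scale="std")` for sensitivity analysis.  Windows
  shrink at the series boundaries.  Zero local MAD means any deviation
  from the window median is flagged (a constant window deviates by zero
  and is kept).
* **Filter realization.**  The fifth-order Butterworth band-pass at a
  0.2 Hz edge and 1000 Hz sampling is ill-conditioned as a single
  transfer function; it is designed and applied as second-order
  sections.  Filtering is zero-phase (forward–backward, doubling the
  effective attenuation) because the pipeline is offline per-trial; a
  causal single pass is available (`zero_phase=False`) for streaming.
* **Normalization.**  Per channel, per trial, population standard
  deviation (ddof = 0); constant channels map to all zeros.  No
  train-set statistics are carried anywhere, so there is no leakage
  between splits.

## Classifiers

The CNN is four blocks of [Conv1d(k=9, 'same') → BatchNorm → ReLU →
MaxPool] with widths 10/20/30/40 and pools 50/10/10; the time axis
shrinks 5000 → 100 → 10 → 1, so the fourth block's pooling is realized
as the global average pool, followed by dropout 0.5 and a dense 40→5
softmax head: 21,655 trainable parameters at 35 input channels
(batch-norm counts 2×C scale/shift parameters; running statistics are
bookkeeping).  Batches are channels-first `(batch, channels, time)`.

The LSTM baseline uses a conv(k=9, width 10) + max-pool(50) front end —
the width mirrors the CNN's first block — a 100-unit LSTM read out at
its final hidden state, dropout, and a dense softmax head.  The SVM
baseline is a one-vs-rest linear SVC (regularization C = 1.0, exposed in
config) on flattened 35×5000 vectors whose margins are softmax-mapped to
a probability-like ranking for confusion reporting.  The random baseline
draws labels uniformly from a seeded generator.

All neural computation runs on a compact NumPy engine (`gaitmotion.nnet`)
with analytically derived backpropagation, verified against central
finite differences in the test suite.  Float32 arithmetic on a fixed
BLAS makes training runs bit-reproducible from their seeds.

Training: Adam (lr 1.5e-3, β₁ = 0.9, β₂ = 0.999), batch 50, 15 epochs,
categorical cross-entropy, stratified 80/20 split.  Stratification
preserves the balanced design the accuracy metric assumes.  There is no
early stopping, validation split or schedule.  `epochs=0` is the
identity.  Aggregates over seeds use the sample standard deviation.

Metric conventions: macro averages are unweighted means over classes;
macro-F1 is the mean of per-class F1s (not the F1 of macro
precision/recall — the suite pins this distinction); precision/recall
are 0 when their denominator is 0 and F1 is 0 when precision+recall
is 0.

## Transfer learning

Leave-one-subject-out: pre-train on the other subjects, then fine-tune
the *entire* network (conv, batch-norm scale/shift, dense) on 10
calibration trials per class at lr 5e-4 while batch-norm forward passes
use the frozen pre-training running statistics (they are neither updated
nor replaced by batch statistics).  Fine-tuning runs 15 epochs — the
epoch count is an open choice fixed here and exposed in
`TransferConfig`; dropout stays active during fine-tuning, matching
pre-training.  The from-scratch variant (`ft_only`) uses the
pre-training hyperparameters but sees only the calibration set; with 50
trials and batch 50 that is 15 gradient steps, which is the designed
reason it lands far below the transferred variants while staying above
the 20 % chance floor.  Evaluation always uses the target holdout, never
the calibration set.

## Deployment

Streams concatenate *raw aligned* trials in seeded random order; each
5-s window is conditioned exactly like a training trial (per-window
z-normalization) before scoring, since the model expects normalized
inputs and a deployed system would not know trial boundaries.  Truth for
a window is the label at its centre row; windows straddling a trial
boundary keep the centre label (the centre row's trial always covers
the majority of a 5-s window when trials are 5 s long).

Kalman smoothing treats each class score as a scalar random walk
(x₀ = 1/5, P₀ = 1, predict P += Q, gain K = P/(P+R)); with the defaults
Q = 2e-3, R = 2e-2 the steady-state gain is
K∞ = M/(M+R), M = (Q+√(Q²+4QR))/2 ≈ 0.27016.  Smoothed scores are not
renormalized across classes before the argmax — under equal steady-state
gains renormalization cannot change the argmax, though it would during
the initial transient; a `renormalize` flag provides the variant.  The
first windows are slightly biased toward the uniform prior, which is
accepted and visible only as a transient.

At the desk scale used in the tests, most sliding windows straddle two
5-s trials, so even a perfect per-trial classifier faces genuinely mixed
windows; absolute stream accuracy is therefore well below per-trial
accuracy.  In this regime smoothing trades lag at class transitions
against suppression of isolated misclassifications, and single short
streams can land several points on either side of the raw accuracy; the
meaningful checks are that trial-aligned single-class streams are
classified perfectly and that smoothing does not degrade window-centre
accuracy in the mean over streams (it typically improves it).

Sensor failure is simulated by zeroing all columns of a sensor group in
the evaluation data only; after conditioning, zero channels remain
exactly zero (constant-channel convention), and the trained model and
training data are untouched.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale as the package's
own smoke configuration: three subjects with 20–24 trials per class
(the generator's default of 100/class reproduces the full study scale),
three training seeds for the CNN, two for the LSTM/SVM baselines, and
streams of 15–40 concatenated trials.  Tolerances follow the quantity:
exact equality for parameter counts and confusion arithmetic, 1e-6 for
softmax normalization and Kalman fixed points, 5 %/1 % passband/stopband
bounds for the filter responses, and ±1 burst for envelope peak counts.

## Known limitations

* The generator's subject-variability ranges are stipulated, not
  estimated from recordings; real inter-subject spread may be larger or
  differently structured.
* The SVM margin-to-probability mapping is a ranking convenience, not a
  calibrated probability.
* Checkpoints store NumPy arrays; they are runtime artifacts, not an
  interchange format.
* Deposited real recordings (35-column CSV trials) can be loaded with
  `read_trial_csv`/`load_dataset` given a manifest, but the adapter path
  is documented rather than exercised in CI, and column headers should
  be introspected before assuming the canonical order.
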