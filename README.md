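# gaitmotion

Motion-intention classification for lower-limb wearables from surface
electromyography (sEMG) and inertial measurement units (IMUs).

Ankle exoskeletons and similar assistive devices need to know, within a
few seconds, *which* functional movement their user is performing —
walking forwards, walking backwards, turning left or right, or squatting
down to pick something up.  `gaitmotion` implements a complete,
reproducible pipeline for this five-class problem:

* **Synthetic data generation** — labeled multichannel trials emulating
  the study montage: 8 sEMG channels (bilateral tibialis anterior,
  gastrocnemius medialis/lateralis, soleus; 12-bit ADC counts at
  1000 Hz) and three 9-axis IMUs (both shanks + right foot, 25 Hz), with
  class-specific muscle-burst timing, stride-periodic kinematics, turn
  yaw-rate signatures, and per-subject variability (gains, latency,
  cadence, noise floors) that makes cross-subject transfer nontrivial.
* **Trial alignment and IO** — linear-interpolation upsampling of the
  IMU streams (×40) into the canonical 5000×35 trial matrix (5 s at
  1000 Hz), CSV trial files and dataset manifests.
* **Signal conditioning** — ADC-to-voltage conversion
  (V = 1.1/4095 · S), Hampel outlier rejection (±25-sample window,
  3σ via 1.4826×MAD), fifth-order Butterworth band-passes
  (0.2–400 Hz for EMG, 0.2–10 Hz for IMU, second-order sections,
  zero-phase), and per-channel z-normalization.
* **Classifiers** — a compact 1-D CNN of four conv–batchnorm–ReLU–maxpool
  blocks (widths 10/20/30/40, kernel 9, pools 50/10/10, global average
  pooling, dropout 0.5, dense softmax head; 21,655 trainable parameters
  at 35 input channels), plus LSTM, linear-SVM and uniform-random
  baselines.  The neural models run on a small seeded NumPy engine with
  hand-derived backpropagation and Adam, so training is bit-reproducible
  on CPU.
* **Training & metrics** — stratified 80/20 splits, Adam (lr 1.5e-3,
  batch 50, 15 epochs, categorical cross-entropy), repeated over seeds;
  accuracy TC/(TC+FC), per-class and macro precision/recall/F1 with
  explicit zero-division conventions.
* **Few-shot transfer** — leave-one-subject-out: pre-train on source
  subjects, fine-tune end-to-end on 10 calibration trials per class at
  lr 5e-4 with batch-norm running statistics frozen, and compare
  pre-trained-only / fine-tuned / from-scratch variants.
* **Deployment** — random concatenation of trials into a continuous
  stream, 5-s sliding windows at 1-s or 2-s strides, per-class scalar
  Kalman smoothing of the probability scores (Q = 2e-3, R = 2e-2;
  steady-state gain K∞ = M/(M+R) with M = (Q+√(Q²+4QR))/2 ≈ 0.270),
  window-centre accuracy, and sensor-failure ablation (zeroing all
  channels of a sensor group in the test data only).

## Worked example

```python
import gaitmotion as gm
from gaitmotion.trial_io import TrialCollection, align_trial
from gaitmotion.preprocess import preprocess_collection

# two subjects, 10 trials per class each -> 100 aligned 5000x35 trials
ds = gm.gen_dataset(2, gm.GeneratorConfig(n_per_class=10, master_seed=1))
coll = preprocess_collection(
    TrialCollection([align_trial(b) for b in ds.bundles]))

train, test = gm.split_dataset(coll, 0.8, seed=0)
model = gm.build_cnn(seed=0)
gm.train_model(model, train, gm.TrainConfig(), seed=0)
report = gm.evaluate(model, test)
print(f"test accuracy {report.accuracy:.3f}")
print(report.confusion)
```

prints (exactly reproducible from the seeds shown):

```
test accuracy 1.000
[[4 0 0 0 0]
 [0 4 0 0 0]
 [0 0 4 0 0]
 [0 0 0 4 0]
 [0 0 0 0 4]]
```

i.e. all 20 held-out trials (4 per class) are classified correctly, and
the per-epoch loss trace (`model.loss_trace`) falls from ≈1.93 to ≈0.40
over the 15 epochs.  The same objects drive the rest of the pipeline:
`gm.transfer_protocol` for leave-one-subject-out adaptation,
`gm.concat_stream` / `gm.classify_stream` / `gm.kalman_smooth` for
continuous classification, and `gm.robustness_report` for sensor
ablations.

A command-line interface wraps the same stages:

```bash
gaitmotion simulate --subjects 2 --per-class 10 --seed 1 --output-dir runs
gaitmotion train runs/dataset/manifest.csv --model cnn --seed 0 --output-dir runs
gaitmotion report-architecture
```

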