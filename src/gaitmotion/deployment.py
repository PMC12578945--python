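"""Continuous-stream classification and sensor-failure robustness.

Deployment is approximated by concatenating trials in random order into one
long multichannel stream, sliding a window equal to the classifier's input
width (5 s) across it at 1 s or 2 s strides, scoring each window, and
optionally smoothing the per-class probability scores with independent
scalar random-walk Kalman filters (process noise Q, measurement noise R).
Accuracy is the fraction of windows whose decision matches the ground-truth
label at the window's central row; windows straddling a trial boundary keep
the centre-row label as truth.

Sensor failure is simulated by zeroing all channels of a named sensor group
in the evaluation data only; the trained model and its training data are
untouched.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import DEFAULT_LAYOUT, ChannelLayout
from .models import ModelHandle
from .preprocess import FilterConfig, preprocess_trial
from .train_eval import evaluate
from .trial_io import CLASS_TO_INDEX, TrialCollection, TrialRecord

__all__ = [
    "Stream", "KalmanConfig", "PredictionTrace", "AblationSpec",
    "concat_stream", "sliding_windows", "classify_stream", "kalman_smooth",
    "kalman_steady_state_gain", "stream_accuracy", "ablate_sensor",
    "robustness_report",
]


@dataclass
class Stream:
    """Concatenated trials: signal (T x channels), per-row truth labels,
    and the row indices where a new trial starts."""

    signal: np.ndarray
    truth: np.ndarray               # per-row class indices
    boundaries: np.ndarray          # ordered trial-change row indices
    sample_rate: float = 1000.0
    channel_names: tuple[str, ...] = field(default_factory=lambda: DEFAULT_LAYOUT.names)

    @property
    def n_rows(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class KalmanConfig:
    """Scalar random-walk filter per class: predict P += Q, gain
    K = P/(P+R)."""

    q: float = 2e-3
    r: float = 2e-2
    x0: float = 0.2          # uniform prior over 5 classes
    p0: float = 1.0

    def __post_init__(self) -> None:
        if self.q <= 0 or self.r <= 0:
            raise ValueError("Q and R must be positive")
        if self.p0 < 0:
            raise ValueError("P0 must be >= 0")


@dataclass
class PredictionTrace:
    """Window-indexed per-class scores from sliding-window inference."""

    center_rows: np.ndarray
    raw_scores: np.ndarray          # (n_windows, n_classes)
    smoothed_scores: np.ndarray
    decisions: np.ndarray
    smoothed: bool = False


def concat_stream(trials: list[TrialRecord] | TrialCollection,
                  order_seed: int = 0) -> Stream:
    """Randomly concatenate trials into one continuous labeled stream."""
    trials = list(trials)
    if not trials:
        raise ValueError("cannot build a stream from zero trials")
    widths = {t.n_channels for t in trials}
    if len(widths) != 1:
        raise ValueError(f"mixed channel widths in stream input: {sorted(widths)}")
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(trials))
    signal_parts = []
    truth_parts = []
    boundaries = []
    row = 0
    for i in order:
        t = trials[i]
        boundaries.append(row)
        signal_parts.append(t.signal)
        truth_parts.append(np.full(t.n_rows, CLASS_TO_INDEX[t.label], dtype=int))
        row += t.n_rows
    first = trials[order[0]]
    return Stream(
        signal=np.concatenate(signal_parts, axis=0),
        truth=np.concatenate(truth_parts),
        boundaries=np.array(boundaries, dtype=int),
        sample_rate=first.sample_rate,
        channel_names=first.channel_names,
    )


def sliding_windows(stream: Stream, window_rows: int, stride_rows: int
                    ) -> list[tuple[int, int]]:
    """(start, center) pairs: starts 0, stride, 2*stride, ... while the
    window fits."""
    if stride_rows < 1:
        raise ValueError("stride must be >= 1 row")
    if window_rows > stream.n_rows:
        raise ValueError(
            f"window of {window_rows} rows exceeds stream length {stream.n_rows}"
        )
    starts = range(0, stream.n_rows - window_rows + 1, stride_rows)
    return [(s, s + window_rows // 2) for s in starts]


def classify_stream(model: ModelHandle, stream: Stream,
                    window_rows: int = 5000, stride_rows: int = 1000,
                    layout: ChannelLayout = DEFAULT_LAYOUT,
                    filter_config: FilterConfig = FilterConfig(),
                    preprocess: bool = True,
                    batch_size: int = 20) -> PredictionTrace:
    """Score every sliding window with the trained model.

    Each window is conditioned exactly like a training trial (per-window
    z-normalization) before scoring, since the model was trained on
    normalized inputs.  ``smoothed_scores`` equals ``raw_scores`` until
    :func:`kalman_smooth` is applied.
    """
    seq_len = model.config.get("seq_len")
    if seq_len is not None and window_rows != seq_len:
        raise ValueError(
            f"window of {window_rows} rows does not match the model's "
            f"expected sequence length {seq_len}"
        )
    windows = sliding_windows(stream, window_rows, stride_rows)
    centers = np.array([c for _, c in windows], dtype=int)
    raw = np.zeros((len(windows), model.n_classes))
    dummy_label = list(CLASS_TO_INDEX)[0]
    for start_idx in range(0, len(windows), batch_size):
        batch = windows[start_idx:start_idx + batch_size]
        mats = []
        for s, _ in batch:
            window = stream.signal[s:s + window_rows]
            record = TrialRecord(signal=window, label=dummy_label,
                                 subject_id="stream",
                                 sample_rate=stream.sample_rate,
                                 channel_names=stream.channel_names)
            if preprocess:
                record = preprocess_trial(record, layout, filter_config)
            mats.append(record.signal.T)
        x = np.stack(mats).astype(np.float32)
        raw[start_idx:start_idx + len(batch)] = model.predict_proba(x)
    return PredictionTrace(
        center_rows=centers,
        raw_scores=raw,
        smoothed_scores=raw.copy(),
        decisions=raw.argmax(axis=1),
        smoothed=False,
    )


def kalman_steady_state_gain(q: float, r: float) -> float:
    """Closed-form steady-state gain of the scalar random-walk filter.

    The Riccati fixed point for the predicted variance is
    M = (Q + sqrt(Q^2 + 4QR)) / 2, giving K = M / (M + R).
    """
    if q <= 0 or r <= 0:
        raise ValueError("Q and R must be positive")
    m = (q + np.sqrt(q * q + 4.0 * q * r)) / 2.0
    return float(m / (m + r))


def kalman_smooth(trace: PredictionTrace,
                  config: KalmanConfig = KalmanConfig(),
                  renormalize: bool = False) -> PredictionTrace:
    """Smooth each class's score sequence with an independent scalar
    filter.

    Per class: x starts at the uniform prior, P at P0; each window does
    P += Q, K = P/(P+R), x += K(z - x), P = (1-K)P.  Decisions are the
    argmax of the smoothed scores.  Scores are not renormalized across
    classes by default (equal steady-state gains leave the argmax unchanged;
    a flag is provided for the renormalized variant).
    """
    raw = trace.raw_scores
    n_windows, n_classes = raw.shape
    smoothed = np.empty_like(raw)
    x = np.full(n_classes, config.x0)
    p = np.full(n_classes, config.p0)
    for w in range(n_windows):
        p = p + config.q
        k = p / (p + config.r)
        x = x + k * (raw[w] - x)
        p = (1.0 - k) * p
        smoothed[w] = x
    if renormalize:
        smoothed = smoothed / smoothed.sum(axis=1, keepdims=True)
    return PredictionTrace(
        center_rows=trace.center_rows.copy(),
        raw_scores=raw.copy(),
        smoothed_scores=smoothed,
        decisions=smoothed.argmax(axis=1),
        smoothed=True,
    )


def stream_accuracy(trace: PredictionTrace, stream: Stream) -> float:
    """Fraction of windows whose decision matches the truth at the window
    centre."""
    truth = stream.truth[trace.center_rows]
    return float(np.mean(trace.decisions == truth))


@dataclass(frozen=True)
class AblationSpec:
    """Zero all channels of one named sensor group in evaluation data."""

    group_name: str
    applied_to: str = "test"


def _zero_columns(signal: np.ndarray, names: tuple[str, ...],
                  group_channel_names: list[str]) -> np.ndarray:
    cols = [i for i, n in enumerate(names) if n in set(group_channel_names)]
    out = signal.copy()
    out[:, cols] = 0.0
    return out


def ablate_sensor(data: "TrialCollection | Stream", spec: AblationSpec,
                  layout: ChannelLayout = DEFAULT_LAYOUT):
    """Return a copy with the group's columns set to exactly zero.

    Other columns are bit-identical; the input is untouched.  Idempotent.
    """
    group_names = layout.group_names(spec.group_name)
    if isinstance(data, Stream):
        return replace(
            data,
            signal=_zero_columns(data.signal, data.channel_names, group_names),
            truth=data.truth.copy(), boundaries=data.boundaries.copy(),
        )
    trials = [
        TrialRecord(
            signal=_zero_columns(t.signal, t.channel_names, group_names),
            label=t.label, subject_id=t.subject_id,
            sample_rate=t.sample_rate, channel_names=t.channel_names)
        for t in data.trials
    ]
    return TrialCollection(trials, data.channel_names)


def robustness_report(model: ModelHandle, test_set: TrialCollection,
                      groups: list[str],
                      layout: ChannelLayout = DEFAULT_LAYOUT) -> dict:
    """Accuracy of the unmodified model on each ablated test-set copy.

    Includes the unablated baseline under the key ``"baseline"``.
    """
    report = {"baseline": evaluate(model, test_set).accuracy}
    for group in groups:
        ablated = ablate_sensor(test_set, AblationSpec(group), layout)
        report[group] = evaluate(model, ablated).accuracy
    return report
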