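"""Training protocol and evaluation metrics.

Training follows a fixed recipe: stratified 80/20 split, Adam at 1.5e-3,
batch size 50, categorical cross-entropy, 15 epochs, no early stopping, no
validation split, no learning-rate schedule; runs are repeated over several
seeds and reported as mean +/- sample standard deviation.

Metrics: accuracy = TC/(TC+FC) over all samples; per-class precision
TP/(TP+FP), recall TP/(TP+FN) and F1 = 2PR/(P+R); summary values are macro
averages (unweighted means over classes, appropriate for the balanced
design).  Zero-division conventions: precision/recall are 0 when their
denominator is 0, F1 is 0 when precision+recall is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnet
from .channels import DEFAULT_LAYOUT, ChannelLayout
from .models import ModelHandle
from .trial_io import TrialCollection, TrialRecord

__all__ = [
    "TrainConfig", "MetricsReport", "split_dataset", "train_model",
    "evaluate", "repeat_runs", "modality_subset", "metrics_from_predictions",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1.5e-3
    batch_size: int = 50
    epochs: int = 15
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    split_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class MetricsReport:
    """Confusion matrix (rows = true, cols = predicted) and derived scores."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray          # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    tc: int                        # true classifications
    fc: int                        # false classifications
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_precision": self.precision.tolist(),
            "per_class_recall": self.recall.tolist(),
            "per_class_f1": self.f1.tolist(),
            "confusion": self.confusion.tolist(),
        }


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             n_classes: int = 5) -> MetricsReport:
    """Build the full metric suite from label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("cannot evaluate on an empty set")
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (y_true, y_pred), 1)
    tp = np.diag(confusion).astype(int)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    tc = int(tp.sum())
    fc = int(confusion.sum() - tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return MetricsReport(
        confusion=confusion,
        accuracy=tc / (tc + fc),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        tc=tc, fc=fc, tp=tp, fp=fp, fn=fn,
    )


def split_dataset(dataset: TrialCollection, fraction: float = 0.8,
                  seed: int = 0) -> tuple[TrialCollection, TrialCollection]:
    """Stratified random train/test split (per-class sizes within 1 of
    fraction*n)."""
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    labels = np.array([t.label.value for t in dataset.trials])
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(
                f"class {cls!r} has {idx.size} trial(s); need >= 2 to split"
            )
        idx = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return dataset.select(sorted(train_idx)), dataset.select(sorted(test_idx))


def _train_net(model: ModelHandle, x: np.ndarray, y: np.ndarray,
               config: TrainConfig, seed: int, lr: "float | None" = None
               ) -> list[float]:
    """Mini-batch Adam optimization of a neural handle; returns the
    per-epoch mean loss trace."""
    rng = np.random.default_rng(seed)
    opt = nnet.Adam(model.net, lr if lr is not None else config.learning_rate)
    trace: list[float] = []
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = model.net.forward(x[batch], training=True)
            loss, dlogits = nnet.softmax_cross_entropy(logits, y[batch])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


def train_model(model: ModelHandle, train_set: TrialCollection,
                config: TrainConfig = TrainConfig(), seed: int = 0
                ) -> ModelHandle:
    """Fit a model handle in place on a trial collection.

    Neural handles run mini-batch Adam with categorical cross-entropy; the
    SVM fits on flattened vectors; the random baseline ignores the data.
    ``epochs=0`` returns the model unchanged with an empty loss trace.
    """
    if len(train_set) == 0:
        raise ValueError("cannot train on an empty dataset")
    x, y = train_set.to_arrays()
    want = model.config.get("in_channels")
    if want is not None and x.shape[1] != want:
        raise ValueError(
            f"model expects {want} channels, training data has {x.shape[1]}"
        )
    n_present = np.unique(y).size
    if model.kind in ("cnn", "lstm", "svm") and n_present < 2:
        raise ValueError(
            f"training requires at least 2 classes present, got {n_present}"
        )
    if model.kind in ("cnn", "lstm"):
        model.loss_trace = _train_net(model, x, y, config, seed)
        model.fitted = True
    elif model.kind == "svm":
        model.estimator.fit(x.reshape(x.shape[0], -1), y)
        model.fitted = True
    elif model.kind == "random":
        model.fitted = True
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    return model


def evaluate(model: ModelHandle, test_set: TrialCollection,
             n_classes: int = 5) -> MetricsReport:
    """Confusion matrix and metric suite from argmax predictions."""
    if len(test_set) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    x, y = test_set.to_arrays()
    y_pred = model.predict(x)
    return metrics_from_predictions(y, y_pred, n_classes)


def repeat_runs(model_factory, dataset: TrialCollection,
                config: TrainConfig = TrainConfig(),
                seeds: "tuple[int, ...] | None" = None) -> dict:
    """Split/train/evaluate once per seed; aggregate mean +/- sample std.

    ``model_factory(seed)`` must return a fresh unfitted handle.
    """
    seeds = tuple(seeds if seeds is not None else config.seeds)
    if len(seeds) < 2:
        raise ValueError("repeat_runs needs at least 2 seeds")
    reports: list[MetricsReport] = []
    for seed in seeds:
        train, test = split_dataset(dataset, config.split_fraction, seed)
        model = model_factory(seed)
        train_model(model, train, config, seed)
        reports.append(evaluate(model, test))
    summary = {}
    for name in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
        vals = np.array([getattr(r, name) for r in reports])
        summary[name] = {"mean": float(vals.mean()),
                         "std": float(vals.std(ddof=1)),
                         "per_seed": vals.tolist()}
    return {"seeds": list(seeds), "summary": summary, "reports": reports}


def modality_subset(dataset: TrialCollection, group_name: str,
                    layout: ChannelLayout = DEFAULT_LAYOUT) -> TrialCollection:
    """Restrict every trial to a named channel group (order preserved).

    Idempotent: subsetting an already-subset collection keeps the channels
    that are still present.
    """
    indices = layout.group(group_name)
    names = [layout.names[i] for i in indices]
    current = list(dataset.channel_names)
    cols = [current.index(n) for n in names if n in current]
    kept = tuple(current[c] for c in cols)
    if not cols:
        raise ValueError(
            f"group {group_name!r} shares no channels with this collection"
        )
    trials = [
        TrialRecord(signal=t.signal[:, cols], label=t.label,
                    subject_id=t.subject_id, sample_rate=t.sample_rate,
                    channel_names=kept)
        for t in dataset.trials
    ]
    return TrialCollection(trials, kept)
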