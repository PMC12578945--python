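"""Leave-one-subject-out few-shot transfer learning.

Protocol: pre-train on all trials of the source subjects, draw a small
calibration set (default 10 trials per class) from the held-out target
subject, and evaluate three variants on the target's remaining trials:

* ``pretrained_only`` — source-trained model, no calibration;
* ``fine_tuned`` — the pre-trained model updated end-to-end on the
  calibration set at a reduced learning rate (5e-4) with batch-norm
  running statistics frozen at their pre-trained values;
* ``ft_only`` — a model trained from scratch on the calibration set alone
  (pre-training hyperparameters, calibration data only).

The holdout never touches any training step, and an empty calibration set
degenerates the fine-tuned variant to the pre-trained one exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import nnet
from .models import ModelHandle
from .train_eval import TrainConfig, evaluate, train_model
from .trial_io import TrialCollection

__all__ = [
    "TransferConfig", "loso_split", "sample_calibration", "fine_tune",
    "transfer_protocol",
]


@dataclass(frozen=True)
class TransferConfig:
    calibration_per_class: int = 10
    finetune_lr: float = 5e-4
    freeze_bn_stats: bool = True
    finetune_epochs: int = 15

    def __post_init__(self) -> None:
        if self.calibration_per_class < 1:
            raise ValueError("calibration_per_class must be >= 1")
        if self.finetune_lr <= 0:
            raise ValueError("finetune_lr must be positive")


def loso_split(dataset: TrialCollection, target_subject: str
               ) -> tuple[TrialCollection, TrialCollection]:
    """Split into (source = all other subjects, target = held-out
    subject)."""
    subjects = set(dataset.subjects)
    if target_subject not in subjects:
        raise ValueError(
            f"unknown subject {target_subject!r}; present: {sorted(subjects)}"
        )
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    src = [i for i, t in enumerate(dataset.trials)
           if t.subject_id != target_subject]
    tgt = [i for i, t in enumerate(dataset.trials)
           if t.subject_id == target_subject]
    return dataset.select(src), dataset.select(tgt)


def sample_calibration(target_set: TrialCollection, k_per_class: int = 10,
                       seed: int = 0) -> tuple[TrialCollection, TrialCollection]:
    """Draw exactly ``k_per_class`` trials per class; the rest is the
    holdout."""
    rng = np.random.default_rng(seed)
    labels = np.array([t.label.value for t in target_set.trials])
    calib_idx: list[int] = []
    hold_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size <= k_per_class:
            raise ValueError(
                f"class {cls!r} has {idx.size} target trials; need more than "
                f"k_per_class={k_per_class} to leave a holdout"
            )
        idx = rng.permutation(idx)
        calib_idx.extend(idx[:k_per_class])
        hold_idx.extend(idx[k_per_class:])
    return target_set.select(sorted(calib_idx)), target_set.select(sorted(hold_idx))


def fine_tune(pretrained: ModelHandle, calibration: TrialCollection,
              config: TransferConfig = TransferConfig(), seed: int = 0,
              train_config: TrainConfig = TrainConfig()) -> ModelHandle:
    """Return a fine-tuned copy of a pre-trained neural model.

    All weights (conv, batch-norm scale/shift, dense) are updated by Adam at
    the reduced learning rate; batch-norm *running statistics* are frozen at
    their pre-trained values and used in place of batch statistics during
    fine-tuning forward passes.  The input model is left untouched.
    """
    if not pretrained.fitted:
        raise ValueError("fine_tune requires a fitted (pre-trained) model")
    if pretrained.kind not in ("cnn", "lstm"):
        raise ValueError("fine-tuning is defined for neural handles")
    model = copy.deepcopy(pretrained)
    if config.finetune_epochs == 0 or len(calibration) == 0:
        return model
    for layer in model.net.layers:
        if isinstance(layer, nnet.BatchNorm1d):
            layer.freeze_stats = config.freeze_bn_stats
    ft_config = TrainConfig(
        learning_rate=config.finetune_lr,
        batch_size=train_config.batch_size,
        epochs=config.finetune_epochs,
        seeds=train_config.seeds,
        split_fraction=train_config.split_fraction,
    )
    train_model(model, calibration, ft_config, seed)
    return model


def transfer_protocol(dataset: TrialCollection, model_factory,
                      train_config: TrainConfig = TrainConfig(),
                      transfer_config: TransferConfig = TransferConfig(),
                      seed: int = 0) -> dict:
    """Run the three-variant LOSO protocol over every subject.

    ``model_factory(seed)`` returns a fresh unfitted handle.  Returns
    per-subject, per-variant accuracies plus across-subject mean +/- sample
    std.
    """
    subjects = sorted(set(dataset.subjects))
    if len(subjects) < 2:
        raise ValueError("transfer protocol needs at least 2 subjects")
    per_subject: dict[str, dict[str, float]] = {}
    for si, subject in enumerate(subjects):
        source, target = loso_split(dataset, subject)
        calibration, holdout = sample_calibration(
            target, transfer_config.calibration_per_class, seed + si)
        pretrained = model_factory(seed + si)
        train_model(pretrained, source, train_config, seed + si)
        acc_pre = evaluate(pretrained, holdout).accuracy
        tuned = fine_tune(pretrained, calibration, transfer_config,
                          seed + si, train_config)
        acc_ft = evaluate(tuned, holdout).accuracy
        scratch = model_factory(seed + si + 1000)
        train_model(scratch, calibration, train_config, seed + si)
        acc_scratch = evaluate(scratch, holdout).accuracy
        per_subject[subject] = {
            "pretrained_only": acc_pre,
            "fine_tuned": acc_ft,
            "ft_only": acc_scratch,
        }
    aggregate = {}
    for variant in ("pretrained_only", "fine_tuned", "ft_only"):
        vals = np.array([per_subject[s][variant] for s in subjects])
        aggregate[variant] = {
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    return {"per_subject": per_subject, "aggregate": aggregate,
            "subjects": subjects}
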