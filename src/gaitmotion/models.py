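"""Classifier construction: the 1-D CNN, an LSTM, a linear SVM and a
chance-level random baseline, with exact trainable-parameter accounting.

The CNN is four blocks of [Conv1d(k=9, 'same') -> BatchNorm -> ReLU ->
MaxPool], with channel widths 10/20/30/40 and pool sizes 50/10/10; after the
third pool the time axis has length 1, so the fourth block's pooling is
realized as the global average pool, followed by dropout(0.5), a dense
40 -> 5 layer and softmax.  With 35 input channels this gives 21,655
trainable parameters.

Batch arrays are channels-first: (batch, channels, time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnet

__all__ = [
    "CnnConfig", "LayerParamCount", "ModelHandle",
    "build_cnn", "build_lstm", "build_svm", "random_classifier",
    "count_parameters", "save_model", "load_model",
]

_POOL_CASCADE = (50, 10, 10)
_BLOCK_CHANNELS = (10, 20, 30, 40)


@dataclass(frozen=True)
class CnnConfig:
    in_channels: int = 35
    seq_len: int = 5000
    kernel: int = 9
    block_channels: tuple[int, ...] = _BLOCK_CHANNELS
    pools: tuple[int, ...] = _POOL_CASCADE
    dropout_p: float = 0.5
    n_classes: int = 5

    def __post_init__(self) -> None:
        if list(self.block_channels) != sorted(self.block_channels):
            raise ValueError("block channel widths must be increasing")
        stride = 1
        for p in self.pools:
            stride *= p
        if self.seq_len <= 0 or self.seq_len % stride:
            raise ValueError(
                f"seq_len {self.seq_len} is not divisible by the pooling "
                f"cascade {'x'.join(map(str, self.pools))}; it must be a "
                f"positive multiple of {stride}"
            )


@dataclass(frozen=True)
class LayerParamCount:
    layer_name: str
    trainable: int
    output_shape: tuple[int, ...]


@dataclass
class ModelHandle:
    """A classifier plus the channel subset it was built for.

    ``kind`` is one of cnn/lstm/svm/random.  Neural models hold a
    :class:`gaitmotion.nnet.Sequential`; the SVM holds a scikit-learn
    estimator.  ``predict_proba`` requires ``fitted`` (the random baseline
    counts as always fitted).
    """

    kind: str
    config: dict
    net: "nnet.Sequential | None" = None
    estimator: object | None = None
    fitted: bool = False
    input_channel_indices: tuple[int, ...] | None = None
    seed: int = 0
    n_classes: int = 5
    loss_trace: list[float] = field(default_factory=list)
    _rng: np.random.Generator | None = None

    def _check_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError(f"{self.kind} model is not fitted")

    def _check_width(self, x: np.ndarray) -> None:
        want = self.config.get("in_channels")
        if want is not None and x.shape[1] != want:
            raise ValueError(
                f"model expects {want} input channels, data has {x.shape[1]}"
            )

    def predict_proba(self, x: np.ndarray, batch_size: int = 50) -> np.ndarray:
        """Per-class scores (rows sum to 1) for a (n, channels, time) batch."""
        self._check_fitted()
        if self.kind in ("cnn", "lstm"):
            self._check_width(x)
            out = []
            for i in range(0, x.shape[0], batch_size):
                logits = self.net.forward(
                    x[i:i + batch_size].astype(np.float32), training=False)
                out.append(nnet.softmax(logits))
            return np.concatenate(out, axis=0)
        if self.kind == "svm":
            self._check_width(x)
            scores = self.estimator.decision_function(x.reshape(x.shape[0], -1))
            if scores.ndim == 1:  # binary: one-vs-rest pair of columns
                scores = np.column_stack([-scores, scores])
            return nnet.softmax(scores)  # probability-like ranking of margins
        if self.kind == "random":
            if self._rng is None:
                self._rng = np.random.default_rng(self.seed)
            labels = self._rng.integers(0, self.n_classes, size=x.shape[0])
            return np.eye(self.n_classes, dtype=float)[labels]
        raise ValueError(f"unknown model kind {self.kind!r}")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def build_cnn(config: CnnConfig = CnnConfig(), seed: int = 0) -> ModelHandle:
    """Assemble the CNN with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    layers: list[nnet.Layer] = []
    cin = config.in_channels
    for bi, cout in enumerate(config.block_channels):
        layers.append(nnet.Conv1d(cin, cout, config.kernel, rng))
        layers.append(nnet.BatchNorm1d(cout))
        layers.append(nnet.ReLU())
        if bi < len(config.pools):
            layers.append(nnet.MaxPool1d(config.pools[bi]))
        cin = cout
    layers.append(nnet.GlobalAvgPool1d())
    layers.append(nnet.Dropout(config.dropout_p, rng))
    layers.append(nnet.Dense(config.block_channels[-1], config.n_classes, rng))
    return ModelHandle(
        kind="cnn",
        config={"in_channels": config.in_channels, "seq_len": config.seq_len,
                "kernel": config.kernel,
                "block_channels": list(config.block_channels),
                "pools": list(config.pools), "dropout_p": config.dropout_p,
                "n_classes": config.n_classes},
        net=nnet.Sequential(layers), seed=seed, n_classes=config.n_classes,
    )


def build_lstm(in_channels: int = 35, seq_len: int = 5000, seed: int = 0,
               hidden: int = 100, front_channels: int = 10,
               front_pool: int = 50, dropout_p: float = 0.5,
               n_classes: int = 5) -> ModelHandle:
    """Sequence-to-label LSTM with a conv + max-pool temporal-downsampling
    front end (width mirroring the CNN's first block), a 100-unit recurrent
    layer read out at its final hidden state, dropout and a dense softmax
    head."""
    if seq_len <= 0 or seq_len % front_pool:
        raise ValueError(
            f"seq_len {seq_len} must be a positive multiple of the "
            f"front-end pool size {front_pool}"
        )
    rng = np.random.default_rng(seed)
    layers: list[nnet.Layer] = [
        nnet.Conv1d(in_channels, front_channels, 9, rng),
        nnet.ReLU(),
        nnet.MaxPool1d(front_pool),
        nnet.TransposeToTimeMajor(),
        nnet.LSTM(front_channels, hidden, rng),
        nnet.Dropout(dropout_p, rng),
        nnet.Dense(hidden, n_classes, rng),
    ]
    return ModelHandle(
        kind="lstm",
        config={"in_channels": in_channels, "seq_len": seq_len,
                "hidden": hidden, "front_channels": front_channels,
                "front_pool": front_pool, "dropout_p": dropout_p,
                "n_classes": n_classes},
        net=nnet.Sequential(layers), seed=seed, n_classes=n_classes,
    )


def build_svm(in_channels: int = 35, seq_len: int = 5000,
              c: float = 1.0, n_classes: int = 5, seed: int = 0) -> ModelHandle:
    """Linear multiclass SVM (one-vs-rest) on flattened channelxtime
    vectors."""
    from sklearn.svm import LinearSVC

    est = LinearSVC(C=c, random_state=seed)
    return ModelHandle(
        kind="svm",
        config={"in_channels": in_channels, "seq_len": seq_len, "C": c,
                "n_classes": n_classes},
        estimator=est, seed=seed, n_classes=n_classes,
    )


def random_classifier(n_classes: int = 5, seed: int = 0) -> ModelHandle:
    """Uniform random label assignment (chance-level baseline)."""
    if n_classes < 2:
        raise ValueError("random classifier needs at least 2 classes")
    return ModelHandle(kind="random", config={"n_classes": n_classes},
                       fitted=True, seed=seed, n_classes=n_classes)


def count_parameters(model: ModelHandle, batch: int = 50
                     ) -> tuple[list[LayerParamCount], int]:
    """Per-layer trainable counts and output shapes, architecture order.

    Conv layers count kernel*c_in*c_out + c_out; batch norms 2*channels
    (scale + shift; running statistics are bookkeeping, not parameters);
    the dense head counts in*out + out.
    """
    if model.kind != "cnn":
        raise ValueError("parameter table is defined for the CNN handle")
    cfg = model.config
    cin = cfg["in_channels"]
    length = cfg["seq_len"]
    k = cfg["kernel"]
    rows = [LayerParamCount("SequenceInput", 0, (batch, cin, length))]
    for bi, cout in enumerate(cfg["block_channels"]):
        rows.append(LayerParamCount(
            f"Conv1D-{bi + 1}", k * cin * cout + cout, (batch, cout, length)))
        rows.append(LayerParamCount(
            f"BatchNorm-{bi + 1}", 2 * cout, (batch, cout, length)))
        rows.append(LayerParamCount(f"ReLU-{bi + 1}", 0, (batch, cout, length)))
        if bi < len(cfg["pools"]):
            length //= cfg["pools"][bi]
            rows.append(LayerParamCount(
                f"MaxPool1D-{bi + 1}", 0, (batch, cout, length)))
        cin = cout
    rows.append(LayerParamCount("GlobalAveragePooling1D", 0, (batch, cin)))
    rows.append(LayerParamCount("Dropout", 0, (batch, cin)))
    n_cls = cfg["n_classes"]
    rows.append(LayerParamCount(
        "FullyConnected", cin * n_cls + n_cls, (batch, n_cls)))
    rows.append(LayerParamCount("Softmax", 0, (batch, n_cls)))
    rows.append(LayerParamCount("Classification", 0, (batch, n_cls)))
    total = sum(r.trainable for r in rows)
    return rows, total


def architecture_table(model: ModelHandle) -> str:
    """Plain-text per-layer parameter table for the CNN."""
    rows, total = count_parameters(model)
    lines = [f"{'Layer (type)':<24}{'Output shape':<20}{'Parameters':>10}"]
    for r in rows:
        shape = "[" + ", ".join(map(str, r.output_shape)) + "]"
        lines.append(f"{r.layer_name:<24}{shape:<20}{r.trainable:>10}")
    lines.append(f"{'Total parameters':<44}{total:>10,}")
    return "\n".join(lines)


def save_model(model: ModelHandle, path: "str | Path") -> Path:
    """Single-file checkpoint: config, weights, channel subset."""
    path = Path(path)
    meta = {"kind": model.kind, "config": model.config,
            "fitted": model.fitted, "seed": model.seed,
            "n_classes": model.n_classes,
            "input_channel_indices": (
                list(model.input_channel_indices)
                if model.input_channel_indices is not None else None)}
    arrays: dict[str, np.ndarray] = {}
    if model.kind in ("cnn", "lstm"):
        arrays = {f"net::{k}": v for k, v in model.net.state().items()}
    elif model.kind == "svm" and model.fitted:
        arrays = {"svm::coef": model.estimator.coef_,
                  "svm::intercept": model.estimator.intercept_,
                  "svm::classes": model.estimator.classes_}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_model(path: "str | Path") -> ModelHandle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    kind, cfg = meta["kind"], meta["config"]
    if kind == "cnn":
        model = build_cnn(CnnConfig(
            in_channels=cfg["in_channels"], seq_len=cfg["seq_len"],
            kernel=cfg["kernel"], block_channels=tuple(cfg["block_channels"]),
            pools=tuple(cfg["pools"]), dropout_p=cfg["dropout_p"],
            n_classes=cfg["n_classes"]), seed=meta["seed"])
    elif kind == "lstm":
        model = build_lstm(cfg["in_channels"], cfg["seq_len"], meta["seed"],
                           cfg["hidden"], cfg["front_channels"],
                           cfg["front_pool"], cfg["dropout_p"],
                           cfg["n_classes"])
    elif kind == "svm":
        model = build_svm(cfg["in_channels"], cfg["seq_len"], cfg["C"],
                          cfg["n_classes"], meta["seed"])
        if meta["fitted"]:
            model.estimator.coef_ = arrays["svm::coef"]
            model.estimator.intercept_ = arrays["svm::intercept"]
            model.estimator.classes_ = arrays["svm::classes"]
    elif kind == "random":
        model = random_classifier(cfg["n_classes"], meta["seed"])
    else:
        raise ValueError(f"unknown model kind {kind!r} in checkpoint")
    if kind in ("cnn", "lstm"):
        model.net.load_state(
            {k.split("::", 1)[1]: v for k, v in arrays.items()})
    model.fitted = meta["fitted"]
    if meta["input_channel_indices"] is not None:
        model.input_channel_indices = tuple(meta["input_channel_indices"])
    return model
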