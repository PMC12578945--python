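"""Trial alignment, CSV persistence and dataset manifests.

A trial is stored as one CSV file: a header row of 35 channel names followed
by 5000 numeric rows — a 5-second recording at 1000 Hz.  The 25 Hz IMU
series are upsampled by the EMG/IMU rate ratio (x40 under defaults) with
linear interpolation before being placed next to the native-rate EMG
columns.  Row index i corresponds to time i/1000 s from trial start;
timestamps are implicit.

A dataset is a directory of trial files plus a delimited manifest with
columns ``trial_path,label,subject_id,seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import DEFAULT_LAYOUT, ChannelLayout
from .synth import MOTION_CLASSES, MotionClass, RawTrialBundle, SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrialRecord",
    "TrialCollection",
    "upsample_linear",
    "align_trial",
    "write_trial_csv",
    "read_trial_csv",
    "write_dataset",
    "load_dataset",
]

CLASS_TO_INDEX = {m: i for i, m in enumerate(MOTION_CLASSES)}


@dataclass
class TrialRecord:
    """Aligned trial matrix (time x channels) with its label and subject."""

    signal: np.ndarray                # (n_rows, n_channels) float
    label: MotionClass
    subject_id: str
    sample_rate: float = 1000.0
    channel_names: tuple[str, ...] = field(default_factory=lambda: DEFAULT_LAYOUT.names)

    def __post_init__(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("trial signal must be 2-D (time x channels)")
        if self.signal.shape[1] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if np.isnan(self.signal).any():
            raise ValueError("trial signal contains missing values")

    @property
    def n_rows(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass
class TrialCollection:
    """Labeled collection of aligned trials, the unit fed to training.

    ``channel_names`` applies to every trial; modality subsetting produces a
    new collection with restricted names and columns.
    """

    trials: list[TrialRecord]
    channel_names: tuple[str, ...] = field(default_factory=lambda: DEFAULT_LAYOUT.names)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def labels(self) -> list[MotionClass]:
        return [t.label for t in self.trials]

    @property
    def subjects(self) -> list[str]:
        return [t.subject_id for t in self.trials]

    def select(self, indices) -> "TrialCollection":
        return TrialCollection([self.trials[i] for i in indices], self.channel_names)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (X, y): X (n, channels, time) float32, y class indices."""
        x = np.stack([t.signal.T for t in self.trials]).astype(np.float32)
        y = np.array([CLASS_TO_INDEX[t.label] for t in self.trials], dtype=np.int64)
        return x, y

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.label.value] = counts.get(t.label.value, 0) + 1
        return counts

    def subject_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.subject_id] = counts.get(t.subject_id, 0) + 1
        return counts


def upsample_linear(series: np.ndarray, factor: int) -> np.ndarray:
    """Upsample a 1-D series by an integer factor with linear interpolation.

    Output positions that coincide with input sample times keep the input
    values; interior positions interpolate between neighbours.  The
    (factor - 1) positions after the last input sample hold the last value
    constant (the boundary is otherwise undefined).
    """
    series = np.asarray(series, dtype=float)
    if factor < 1:
        raise ValueError(f"upsampling factor must be >= 1, got {factor}")
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    n = series.size
    fine = np.arange(n * int(factor)) / float(factor)
    # np.interp clamps beyond the last coarse sample -> constant hold tail
    return np.interp(fine, np.arange(n), series)


def align_trial(bundle: RawTrialBundle,
                layout: ChannelLayout = DEFAULT_LAYOUT) -> TrialRecord:
    """Convert a native-rate bundle into the aligned time x 35 trial matrix.

    IMU channels are upsampled by the (integer) EMG/IMU length ratio and the
    columns ordered per the canonical layout: 8 EMG, then each IMU unit as
    accel xyz, gyro xyz, mag xyz.
    """
    n_emg = bundle.emg.shape[1]
    n_imu = bundle.imu.shape[2]
    ratio = n_emg / n_imu
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"EMG/IMU length ratio {ratio} is not an integer upsampling factor"
        )
    factor = int(round(ratio))
    n_channels = bundle.emg.shape[0] + bundle.imu.shape[0] * bundle.imu.shape[1]
    if n_channels != layout.n_channels:
        raise ValueError(
            f"bundle has {n_channels} channels but layout expects {layout.n_channels}"
        )
    columns = [bundle.emg[i].astype(float) for i in range(bundle.emg.shape[0])]
    for unit in range(bundle.imu.shape[0]):
        for axis in range(bundle.imu.shape[1]):
            up = upsample_linear(bundle.imu[unit, axis], factor)
            if abs(up.size - n_emg) > factor:
                raise ValueError(
                    f"upsampled IMU length {up.size} deviates from {n_emg} "
                    f"by more than one coarse sample"
                )
            if up.size < n_emg:            # zero-order hold the tail
                up = np.concatenate([up, np.full(n_emg - up.size, up[-1])])
            columns.append(up[:n_emg])
    signal = np.column_stack(columns)
    return TrialRecord(signal=signal, label=bundle.label,
                       subject_id=bundle.subject_id,
                       channel_names=layout.names)


def write_trial_csv(trial: TrialRecord, path: "str | Path") -> Path:
    """Write one trial as a CSV: header of channel names + numeric rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(trial.signal, columns=list(trial.channel_names))
    df.to_csv(path, index=False)
    return path


def read_trial_csv(path: "str | Path", layout: ChannelLayout = DEFAULT_LAYOUT,
                   label: "MotionClass | str | None" = None,
                   subject_id: str = "unknown",
                   expected_rows: "int | None" = None) -> TrialRecord:
    """Read a trial CSV, validating shape and header against the layout.

    The CSV itself carries no label; pass ``label``/``subject_id`` (usually
    from the dataset manifest) to populate the record.
    """
    path = Path(path)
    df = pd.read_csv(path)
    names = tuple(df.columns)
    if names != tuple(layout.names):
        if len(names) != layout.n_channels:
            raise ValueError(
                f"{path}: expected {layout.n_channels} columns, found {len(names)}"
            )
        bad = [(i, a, b) for i, (a, b) in enumerate(zip(names, layout.names)) if a != b]
        i, found, want = bad[0]
        raise ValueError(
            f"{path}: column {i} named {found!r}, expected {want!r}"
        )
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        row, col = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at row {row}, "
            f"column {names[col]!r}"
        )
    if expected_rows is not None and values.shape[0] != expected_rows:
        raise ValueError(
            f"{path}: expected {expected_rows} rows, found {values.shape[0]}"
        )
    mlabel = MotionClass.from_label(label) if label is not None else MotionClass.walk_forward
    return TrialRecord(signal=values, label=mlabel, subject_id=subject_id,
                       channel_names=layout.names)


def write_dataset(dataset: SyntheticDataset, out_dir: "str | Path",
                  layout: ChannelLayout = DEFAULT_LAYOUT) -> Path:
    """Align and write every bundle of a synthetic dataset plus a manifest.

    Returns the manifest path.  Trial files go under ``out_dir/trials/``.
    """
    out_dir = Path(out_dir)
    trials_dir = out_dir / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, bundle in enumerate(dataset.bundles):
        rel = Path("trials") / f"trial_{i:05d}.csv"
        record = align_trial(bundle, layout)
        write_trial_csv(record, out_dir / rel)
        rows.append({
            "trial_path": str(rel),
            "label": bundle.label.value,
            "subject_id": bundle.subject_id,
            "seed": bundle.seed,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["trial_path", "label", "subject_id", "seed"]
                 ).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: "str | Path",
                 layout: ChannelLayout = DEFAULT_LAYOUT) -> TrialCollection:
    """Load every trial referenced by a manifest into a collection."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if df.empty:
        logger.warning("manifest %s lists no trials", manifest_path)
        return TrialCollection([], layout.names)
    paths = df["trial_path"].tolist()
    dupes = {p for p in paths if paths.count(p) > 1}
    if dupes:
        raise ValueError(f"duplicate trial paths in manifest: {sorted(dupes)}")
    missing = [p for p in paths
               if not (manifest_path.parent / p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    trials = []
    for row in df.itertuples(index=False):
        label = MotionClass.from_label(row.label)   # errors on unknown labels
        trials.append(read_trial_csv(manifest_path.parent / row.trial_path,
                                     layout, label=label,
                                     subject_id=str(row.subject_id)))
    coll = TrialCollection(trials, layout.names)
    logger.info("loaded %d trials; per-class %s; per-subject %s",
                len(coll), coll.class_counts(), coll.subject_counts())
    return coll
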