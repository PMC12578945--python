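"""Flat pipeline configuration, serializable to/from YAML.

One file with per-module sections (generator, filters, train, transfer,
kalman, plus output directory and log level); defaults reproduce the
standard settings used throughout the package.  CLI flags override file
values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deployment import KalmanConfig
from .preprocess import FilterConfig
from .synth import GeneratorConfig
from .train_eval import TrainConfig
from .transfer import TransferConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    n_subjects: int = 3
    output_dir: str = "runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                d = dataclasses.asdict(value)
                out[f.name] = {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in d.items()}
            else:
                out[f.name] = value
        return out


_SECTION_TYPES = {
    "generator": GeneratorConfig,
    "filters": FilterConfig,
    "train": TrainConfig,
    "transfer": TransferConfig,
    "kalman": KalmanConfig,
}


def _build_section(cls, data: dict):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ValueError(
            f"invalid config key(s) {sorted(unknown)} for section "
            f"{cls.__name__}; valid keys: {sorted(valid)}"
        )
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: "str | Path | None" = None,
                overrides: "dict | None" = None) -> PipelineConfig:
    """Load a YAML pipeline config; missing sections take defaults.

    ``overrides`` maps ``section.key`` strings to values (CLI flags).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for dotted, value in (overrides or {}).items():
        section, _, key = dotted.partition(".")
        if key:
            data.setdefault(section, {})[key] = value
        else:
            data[section] = value
    kwargs = {}
    for name, value in data.items():
        if name in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(_SECTION_TYPES[name], value)
        elif name in ("n_subjects", "output_dir", "log_level"):
            kwargs[name] = value
        else:
            raise ValueError(
                f"invalid config key {name!r}; valid top-level keys: "
                f"{sorted([*_SECTION_TYPES, 'n_subjects', 'output_dir', 'log_level'])}"
            )
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
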