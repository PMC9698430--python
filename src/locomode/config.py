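"""Structured run configuration for the pipeline and its CLI.

One YAML document describes a full run: which label schema, the simulator
settings, the windowing geometry, the architecture, and the optimizer
hyperparameters.  Every CLI flag overrides its config key.  Configs
round-trip through serialization so a run manifest can reproduce a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .training import TrainConfig


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass
class RunConfig:
    """Everything needed to execute the pipeline end to end."""

    schema: str = "enabl3s"
    seed: int = 0
    # simulator
    minutes: float = 4.0
    n_imus: int = 2
    sample_rate: float = 500.0
    noise_scale: float = 1.0
    # windowing
    window_s: float = 1.3
    stride_s: float = 0.05
    transition_half_width_s: float = 0.25
    # architecture
    arch: str = "cnn_lstm"
    hidden_profile: tuple[int, ...] | None = None
    activation: str = "relu"
    dropout: float = 0.25
    # optimization
    train: TrainConfig = field(default_factory=TrainConfig)
    # outputs
    workdir: str = "runs/run0"

    def __post_init__(self) -> None:
        problems = []
        if self.schema not in ("enabl3s", "myleg"):
            problems.append(f"unknown schema {self.schema!r}")
        if self.arch not in ("cnn", "cnn_gru", "cnn_lstm"):
            problems.append(f"unknown architecture {self.arch!r}")
        if self.n_imus not in (1, 2):
            problems.append(f"n_imus must be 1 or 2, got {self.n_imus}")
        if self.minutes <= 0 or self.window_s <= 0 or self.stride_s <= 0:
            problems.append("minutes, window_s and stride_s must be positive")
        if problems:
            raise ConfigError("; ".join(problems))
        if self.hidden_profile is not None:
            self.hidden_profile = tuple(self.hidden_profile)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["hidden_profile"] is not None:
            d["hidden_profile"] = list(d["hidden_profile"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "train" in data and isinstance(data["train"], dict):
            try:
                data["train"] = TrainConfig(**data["train"])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid train section: {exc}") from None
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
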