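"""Configuration dataclasses, YAML (de)serialization and named presets.

Two presets ship with the package:

``desk``
    A small configuration (32x32 images, 2 levels, 4 steps) sized so the full
    pipeline — phantom generation, training, basis construction, enhancement
    and evaluation — runs on a single CPU in minutes. This is the default for
    all tests and examples.

``paper512``
    The full-scale configuration used for real 512x512 PA chest radiographs
    (7 levels, 32 steps per level, 22 epochs, minibatch 4). Provided for
    completeness; training it requires multi-GPU hardware and is never run by
    the test-suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError


@dataclass
class FlowConfig:
    """Architecture and training hyperparameters of the coupling flow.

    ``sv_min``/``sv_max`` are the singular-value crop bounds applied to every
    invertible 1x1 convolution weight at the end of each epoch; they guarantee
    a condition number of at most ``sv_max / sv_min`` and hence invertibility.
    """

    image_size: int = 32
    channels: int = 1
    n_levels: int = 2
    n_steps: int = 4
    n_coupling_convs: int = 3
    kernel_size: int = 3
    hidden_width: int = 64
    sv_min: float = 1e-3
    sv_max: float = 1e3
    batch_size: int = 16
    n_epochs: int = 4
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ParameterError("n_levels must be >= 1")
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")
        if self.image_size % (2 ** self.n_levels) != 0:
            raise ParameterError(
                f"image_size={self.image_size} must be divisible by "
                f"2^n_levels={2 ** self.n_levels}"
            )
        if not (0 < self.sv_min < self.sv_max):
            raise ParameterError("require 0 < sv_min < sv_max")
        if self.n_coupling_convs < 1:
            raise ParameterError("n_coupling_convs must be >= 1")

    @property
    def latent_dim(self) -> int:
        return self.image_size ** 2 * self.channels


@dataclass
class EnhanceParams:
    """Latent-space enhancement parameters.

    gamma
        Interpolation fraction of the L-infinity step (0 <= gamma <= 1 in
        ``linf`` mode). In ``euclidean`` mode it is the extrapolation strength
        and values > 1 enhance. Default 0.2.
    beta
        Final Euclidean extrapolation factor (>= 1) applied after the
        L-infinity interpolation. Default 1.2. Values much above 2 tend to
        cause large local or global deformation; a warning is emitted.
    mode
        ``"linf"`` (three-step scheme, the default) or ``"euclidean"``
        (single-step extrapolation, kept for ablation).
    """

    gamma: float = 0.2
    beta: float = 1.2
    mode: str = "linf"
    beta_warn_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("linf", "euclidean"):
            raise ParameterError(f"unknown enhancement mode {self.mode!r}")
        if self.gamma < 0:
            raise ParameterError("gamma must be >= 0")
        if self.mode == "linf":
            if self.gamma > 1:
                raise ParameterError("in linf mode gamma must be in [0, 1]")
            if self.beta < 1:
                raise ParameterError("in linf mode beta must be >= 1")


@dataclass
class PreprocessConfig:
    """Geometry and windowing policy of the preprocessing chain."""

    canvas_size: int = 64
    model_size: int = 32
    display_size: int = 64
    invert_monochrome1: bool = True


@dataclass
class RunConfig:
    """Top-level configuration tying one pipeline run together."""

    flow: FlowConfig = field(default_factory=FlowConfig)
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: int = 0
    log_level: str = "INFO"


_PRESETS: dict[str, dict[str, Any]] = {
    "desk": {},
    "paper512": {
        "flow": {
            "image_size": 512,
            "channels": 1,
            "n_levels": 7,
            "n_steps": 32,
            "n_coupling_convs": 3,
            "kernel_size": 3,
            "hidden_width": 512,
            "batch_size": 4,
            "n_epochs": 22,
        },
        "preprocess": {
            "canvas_size": 1024,
            "model_size": 512,
            "display_size": 1024,
        },
    },
}


def _from_dict(cls, data: dict[str, Any]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ParameterError(f"unknown {cls.__name__} field {key!r}")
        ftype = fields[key].type
        if isinstance(value, dict) and ftype in ("FlowConfig", "EnhanceParams", "PreprocessConfig"):
            value = _from_dict({"FlowConfig": FlowConfig,
                                "EnhanceParams": EnhanceParams,
                                "PreprocessConfig": PreprocessConfig}[ftype], value)
        kwargs[key] = value
    return cls(**kwargs)


def preset(name: str) -> RunConfig:
    """Return a named configuration preset (``desk`` or ``paper512``)."""
    if name not in _PRESETS:
        raise ParameterError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return _from_dict(RunConfig, _PRESETS[name])


def to_dict(cfg) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def dump_yaml(cfg: RunConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(to_dict(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_yaml(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} does not contain a mapping")
    return _from_dict(RunConfig, data)
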