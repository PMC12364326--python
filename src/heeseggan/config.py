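"""Run configuration: nested sections, strict YAML loading, hashing.

Unknown keys are rejected so typos never silently fall back to defaults;
a resolved snapshot plus its hash is written with every CLI run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .discriminator import DiscriminatorConfig
from .errors import ConfigurationError
from .generator import GeneratorConfig
from .phantom import PhantomConfig
from .preprocessing import WindowSpec
from .training import TrainConfig

__all__ = ["RunConfig", "DataConfig", "PreprocessingConfig", "LossesConfig",
           "ProtocolConfig", "EvaluationConfig", "config_hash"]


@dataclass(frozen=True)
class DataConfig:
    n_train: int = 64
    n_test: int = 16
    phantom: PhantomConfig = field(default_factory=PhantomConfig)


@dataclass(frozen=True)
class PreprocessingConfig:
    window_level: float = -600.0
    window_width: float = 1200.0
    roi_size: int = 128
    edge_method: str = "boundary"

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_level, self.window_width)


@dataclass(frozen=True)
class LossesConfig:
    omega_e: float = 1.0
    omega_s: float = 1.0
    use_lds: bool = True
    use_lge: bool = True
    use_dice: bool = True


@dataclass(frozen=True)
class ProtocolConfig:
    batch_size: int = 64
    lr: float = 0.001
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 2
    seed: int = 0
    clip_range: tuple[float, float] = (-0.012, 0.012)
    lr_floor: float = 1e-5
    d_steps: int = 1
    adversarial: bool = True
    plateau_patience: int = 0
    plateau_tol: float = 1e-4


@dataclass(frozen=True)
class EvaluationConfig:
    threshold: float = 0.5
    aggregation: str = "macro"


@dataclass(frozen=True)
class RunConfig:
    data: DataConfig = field(default_factory=DataConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    losses: LossesConfig = field(default_factory=LossesConfig)
    training: ProtocolConfig = field(default_factory=ProtocolConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    # -- resolution --------------------------------------------------------
    def resolved_train_config(self) -> TrainConfig:
        """Merge all sections into the flat trainer configuration."""
        if self.discriminator.input_size != self.preprocessing.roi_size:
            raise ConfigurationError(
                f"discriminator.input_size ({self.discriminator.input_size}) "
                f"must equal preprocessing.roi_size ({self.preprocessing.roi_size})")
        tr, g, d, lo = self.training, self.generator, self.discriminator, self.losses
        return TrainConfig(
            batch_size=tr.batch_size, lr=tr.lr, betas=tr.betas,
            epochs=tr.epochs, seed=tr.seed, clip_range=tr.clip_range,
            lr_floor=tr.lr_floor, d_steps=tr.d_steps,
            image_size=self.preprocessing.roi_size, channels=g.in_channels,
            adversarial=tr.adversarial, use_mb=d.use_minibatch,
            use_ir=g.use_inverted_residual, fusion=g.fusion,
            use_lds=lo.use_lds, use_lge=lo.use_lge, use_dice=lo.use_dice,
            omega_e=lo.omega_e, omega_s=lo.omega_s,
            gen_widths=g.base_widths, gen_expansion=g.expansion_factor,
            disc_widths=d.widths, mb_out_dim=d.mb_out_dim,
            mb_sigma_mode=d.mb_sigma_mode, mb_sigma_value=d.mb_sigma_value,
            dropout_rate=d.dropout_rate,
            plateau_patience=tr.plateau_patience, plateau_tol=tr.plateau_tol,
            threshold=self.evaluation.threshold,
        )


def _build(cls, data: dict, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"section {path or '<root>'} must be a mapping")
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_map)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section {path or '<root>'}")
    kwargs = {}
    for name, value in data.items():
        f = field_map[name]
        here = f"{path}.{name}" if path else name
        default = _field_default(f)
        if dataclasses.is_dataclass(f.type) or dataclasses.is_dataclass(default):
            target = f.type if dataclasses.is_dataclass(f.type) else type(default)
            kwargs[name] = _build(target, value, here)
        elif isinstance(default, tuple) and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _field_default(f: dataclasses.Field):
    if f.default is not dataclasses.MISSING:
        return f.default
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        return f.default_factory()
    return None


def config_hash(config: RunConfig | dict) -> str:
    """Stable hash of the resolved configuration."""
    data = config.to_dict() if isinstance(config, RunConfig) else config
    canonical = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
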