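"""Alternating adversarial optimization and run management.

Per iteration the discriminator minimizes ``-L_a`` on detached predictions
and is weight-clipped; the generator then minimizes
``L_a + w_e*L_ge + w_s*L_gs`` plus the multi-level mask supervision
``L_ds``.  ``L_ds`` is bookkept inside ``L_d = -L_a - L_ds`` but its
gradient can only act through the generator (the discriminator has no
parameters in it), so it is applied during the generator update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

from .discriminator import (Discriminator, DiscriminatorConfig,
                            build_discriminator, clip_weights)
from .errors import ConfigurationError, TrainingDiverged
from .generator import GeneratorConfig, HedUNetGenerator, build_generator
from .losses import (LossReport, LossWeights, adversarial_loss,
                     aggregated_mask_loss, dice_loss, edge_loss,
                     generator_loss)
from .nn import Adam, CosineAnnealingLR, Tensor
from .phantom import PhantomSample
from .preprocessing import WindowSpec, composite_from_volume

__all__ = ["TrainConfig", "TrainingExample", "Trainer", "train", "predict",
           "composites_from_phantoms", "ablation_config", "ABLATIONS",
           "LOSS_ABLATIONS", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    lr: float = 0.001
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 2
    seed: int = 0
    clip_range: tuple[float, float] = (-0.012, 0.012)
    lr_floor: float = 1e-5
    d_steps: int = 1
    image_size: int = 128
    channels: Literal[1, 3] = 3
    # architecture / mechanism toggles
    adversarial: bool = True
    use_mb: bool = True
    use_ir: bool = True
    fusion: Literal["attention", "last"] = "attention"
    # loss toggles and weights
    use_lds: bool = True
    use_lge: bool = True
    use_dice: bool = True
    omega_e: float = 1.0
    omega_s: float = 1.0
    # network widths
    gen_widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    gen_expansion: int = 4
    disc_widths: tuple[int, int, int, int] = (16, 32, 64, 128)
    mb_out_dim: int = 4
    mb_sigma_mode: Literal["as_printed", "fixed"] = "fixed"
    mb_sigma_value: float = 1.0
    dropout_rate: float = 0.20
    # stopping / misc
    total_iterations: int | None = None  # scheduler horizon; derived if None
    plateau_patience: int = 0   # 0 disables the plateau detector
    plateau_tol: float = 1e-4
    threshold: float = 0.5

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        if self.adversarial and self.use_mb and self.batch_size < 2:
            raise ConfigurationError(
                "minibatch discrimination needs batch_size >= 2")
        if self.channels not in (1, 3):
            raise ConfigurationError("channels must be 1 or 3")

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            in_channels=self.channels, base_widths=self.gen_widths,
            expansion_factor=self.gen_expansion,
            use_inverted_residual=self.use_ir, fusion=self.fusion)

    def discriminator_config(self) -> DiscriminatorConfig:
        return DiscriminatorConfig(
            in_channels=self.channels, widths=self.disc_widths,
            dropout_rate=self.dropout_rate, input_size=self.image_size,
            mb_out_dim=self.mb_out_dim, mb_sigma_mode=self.mb_sigma_mode,
            mb_sigma_value=self.mb_sigma_value, use_minibatch=self.use_mb,
            clip_range=self.clip_range)

    def loss_weights(self) -> LossWeights:
        return LossWeights(self.omega_e, self.omega_s)


@dataclass
class TrainingExample:
    image: np.ndarray                 # (C, H, W) in [0, 1]
    mask: np.ndarray                  # (H, W) binary
    mask_pyramid: list[np.ndarray]    # y_d levels
    edge_pyramid: list[np.ndarray]    # y_g levels


def composites_from_phantoms(samples: Sequence[PhantomSample], *,
                             size: int = 128, channels: int = 3,
                             spec: WindowSpec = WindowSpec()) -> list[TrainingExample]:
    """Preprocess phantoms into model-ready training examples."""
    out = []
    for sample in samples:
        image, mask, y_d, y_g = composite_from_volume(
            sample.volume, sample.mask_volume, size=size, spec=spec)
        nchw = image.as_nchw()
        if channels == 1:
            nchw = nchw[1:2]  # keep only the current slice
        out.append(TrainingExample(nchw, mask, y_d.levels, y_g.levels))
    return out


def _stack(examples: Sequence[TrainingExample]):
    images = np.stack([e.image for e in examples])
    masks = np.stack([e.mask for e in examples]).astype(np.float64)
    n_levels = len(examples[0].mask_pyramid)
    yd = [np.stack([e.mask_pyramid[k] for e in examples]) for k in range(n_levels)]
    yg = [np.stack([e.edge_pyramid[k] for e in examples]) for k in range(n_levels)]
    return images, masks, yd, yg


class Trainer:
    """Owns the networks, optimizers, schedulers and RNG streams."""

    def __init__(self, config: TrainConfig):
        self.config = config
        init_rng = np.random.default_rng(config.seed)
        self.rng = np.random.default_rng(config.seed + 1)  # batching + dropout
        self.generator: HedUNetGenerator = build_generator(
            config.generator_config(), init_rng)
        self.discriminator: Discriminator | None = None
        self.opt_d = self.sched_d = None
        if config.adversarial:
            self.discriminator = build_discriminator(
                config.discriminator_config(), init_rng, dropout_rng=self.rng)
            self.opt_d = Adam(list(self.discriminator.parameters()),
                              lr=config.lr, betas=config.betas)
        self.opt_g = Adam(list(self.generator.parameters()),
                          lr=config.lr, betas=config.betas)
        self.sched_g: CosineAnnealingLR | None = None
        self.iteration = 0
        self.history: list[LossReport] = []

    # -- single optimization step -----------------------------------------
    def step(self, images, masks, yd_levels, yg_levels) -> LossReport:
        cfg = self.config
        n, _, h, w = images.shape
        x = Tensor(images)
        report = LossReport(iteration=self.iteration)

        pred = self.generator(x)
        yhat = pred.mask_prob                     # (N, H, W)
        if not np.isfinite(yhat.data).all():
            raise TrainingDiverged(
                f"non-finite generator output at iteration {self.iteration}",
                snapshot={
                    "iteration": self.iteration,
                    "param_norm": float(np.sqrt(sum(
                        np.square(p.data).sum()
                        for p in self.generator.parameters()))),
                })

        if cfg.adversarial:
            yhat_const = Tensor(yhat.data.reshape(n, 1, h, w))
            real_in = x * Tensor(masks.reshape(n, 1, h, w))
            for _ in range(cfg.d_steps):
                fake_in = x * yhat_const
                _, mean_fake, _ = self.discriminator.score(fake_in)
                _, mean_real, _ = self.discriminator.score(real_in)
                l_a_d = adversarial_loss(mean_fake, mean_real)
                loss_d = -l_a_d  # L_ds holds no discriminator parameters
                self.opt_d.zero_grad()
                loss_d.backward()
                self.opt_d.step()
                clip_weights(self.discriminator, cfg.clip_range)
                if self.sched_d is not None:
                    self.sched_d.step()

        # generator update
        zero = Tensor(0.0)
        l_a = zero
        if cfg.adversarial:
            fake_in = x * yhat.reshape(n, 1, h, w)
            _, mean_fake, _ = self.discriminator.score(fake_in)
            _, mean_real, _ = self.discriminator.score(
                x * Tensor(masks.reshape(n, 1, h, w)))
            l_a = adversarial_loss(mean_fake, mean_real)

        l_ds = zero
        if cfg.use_lds:
            l_ds, per_mask, w_mask = aggregated_mask_loss(
                pred.side.native, yd_levels)
            report.per_level_mask = [float(t.item()) for t in per_mask]
            report.balance_weights_mask = [np.asarray(v).tolist() for v in w_mask]
        l_ge = zero
        if cfg.use_lge:
            l_ge, per_edge, w_edge = edge_loss(pred.side.native, yg_levels)
            report.per_level_edge = [float(t.item()) for t in per_edge]
            report.balance_weights_edge = [np.asarray(v).tolist() for v in w_edge]
        l_gs = dice_loss(yhat, masks) if cfg.use_dice else zero

        l_g = generator_loss(l_a, l_ge, l_gs, cfg.loss_weights())
        total = (l_g + l_ds) if cfg.use_lds else l_g

        self.opt_g.zero_grad()
        if self.discriminator is not None:
            self.discriminator.zero_grad()
        total.backward()
        self.opt_g.step()
        if self.sched_g is not None:
            report.lr = self.sched_g.step()

        report.L_a = float(l_a.item())
        report.L_ds = float(l_ds.item())
        report.L_d = -report.L_a - report.L_ds
        report.L_ge = float(l_ge.item())
        report.L_gs = float(l_gs.item())
        report.L_g = float(l_g.item())
        self.iteration += 1
        if not report.all_finite():
            raise TrainingDiverged(
                f"non-finite loss at iteration {report.iteration}",
                snapshot={
                    "iteration": report.iteration,
                    "losses": report.as_dict(),
                    "param_norm": float(np.sqrt(sum(
                        (p.data ** 2).sum()
                        for p in self.generator.parameters()))),
                })
        return report

    # -- training loop ----------------------------------------------------
    def fit(self, dataset: Sequence[TrainingExample],
            iterations: int | None = None) -> list[LossReport]:
        cfg = self.config
        if iterations is None:
            iterations = cfg.epochs * max(1, len(dataset) // cfg.batch_size)
        if self.sched_g is None:
            horizon = cfg.total_iterations or iterations
            self.sched_g = CosineAnnealingLR(self.opt_g, horizon, cfg.lr_floor)
            if self.opt_d is not None:
                self.sched_d = CosineAnnealingLR(
                    self.opt_d, horizon * cfg.d_steps, cfg.lr_floor)

        self.generator.train()
        if self.discriminator is not None:
            self.discriminator.train()

        batch = min(cfg.batch_size, len(dataset))
        new_reports = []
        iters_per_epoch = max(1, len(dataset) // batch)
        epoch_losses: list[float] = []
        while self.iteration < iterations:
            idx = self.rng.choice(len(dataset), size=batch, replace=False)
            images, masks, yd, yg = _stack([dataset[i] for i in idx])
            report = self.step(images, masks, yd, yg)
            self.history.append(report)
            new_reports.append(report)
            if cfg.plateau_patience and self.iteration % iters_per_epoch == 0:
                epoch_losses.append(np.mean(
                    [r.L_g for r in new_reports[-iters_per_epoch:]]))
                if _plateaued(epoch_losses, cfg.plateau_patience, cfg.plateau_tol):
                    break
        return new_reports

    # -- inference ---------------------------------------------------------
    def predict(self, images: np.ndarray,
                threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic inference; returns (binary masks, probabilities)."""
        threshold = self.config.threshold if threshold is None else threshold
        self.generator.eval()
        try:
            probs = self.generator(Tensor(np.asarray(images))).mask_prob.data
        finally:
            self.generator.train()
        return (probs >= threshold).astype(np.uint8), probs

    # -- serialization -----------------------------------------------------
    def state(self) -> dict:
        arrays = {}
        for name, arr in self.generator.state_dict().items():
            arrays[f"gen.{name}"] = arr
        for name, arr in self.opt_g.state_dict().items():
            arrays[f"optg.{name}"] = arr
        if self.discriminator is not None:
            for name, arr in self.discriminator.state_dict().items():
                arrays[f"disc.{name}"] = arr
            for name, arr in self.opt_d.state_dict().items():
                arrays[f"optd.{name}"] = arr
        meta = {
            "config": asdict(self.config),
            "iteration": self.iteration,
            "rng_state": self.rng.bit_generator.state,
            "sched_g": None if self.sched_g is None else
                {"t": self.sched_g.t, "t_max": self.sched_g.t_max,
                 "base_lr": self.sched_g.base_lr},
            "sched_d": None if self.sched_d is None else
                {"t": self.sched_d.t, "t_max": self.sched_d.t_max,
                 "base_lr": self.sched_d.base_lr},
        }
        return {"arrays": arrays, "meta": meta}

    @classmethod
    def from_state(cls, state: dict) -> "Trainer":
        meta = state["meta"]
        cfg_dict = dict(meta["config"])
        for key in ("betas", "clip_range", "gen_widths", "disc_widths"):
            if key in cfg_dict and isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        trainer = cls(TrainConfig(**cfg_dict))
        arrays = state["arrays"]
        trainer.generator.load_state_dict(_subdict(arrays, "gen."))
        trainer.opt_g.load_state_dict(_subdict(arrays, "optg."))
        if trainer.discriminator is not None:
            trainer.discriminator.load_state_dict(_subdict(arrays, "disc."))
            trainer.opt_d.load_state_dict(_subdict(arrays, "optd."))
        trainer.iteration = int(meta["iteration"])
        trainer.rng.bit_generator.state = meta["rng_state"]
        for name, opt in (("sched_g", trainer.opt_g), ("sched_d", trainer.opt_d)):
            info = meta[name]
            if info is not None:
                sched = CosineAnnealingLR(opt, info["t_max"],
                                          trainer.config.lr_floor)
                sched.base_lr = info["base_lr"]
                sched.t = info["t"]
                setattr(trainer, name, sched)
        return trainer


def _subdict(arrays: dict, prefix: str) -> dict:
    return {k[len(prefix):]: v for k, v in arrays.items() if k.startswith(prefix)}


def _plateaued(epoch_losses, patience, tol) -> bool:
    if len(epoch_losses) < patience + 1:
        return False
    ref = epoch_losses[-patience - 1]
    recent = epoch_losses[-patience:]
    return all(abs(v - ref) <= tol * max(abs(ref), 1e-12) for v in recent)


def save_checkpoint(trainer: Trainer, path) -> None:
    state = trainer.state()
    np.savez(path, __meta__=json.dumps(state["meta"]), **state["arrays"])


def load_checkpoint(path) -> Trainer:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    return Trainer.from_state({"meta": meta, "arrays": arrays})


def train(dataset: Sequence[TrainingExample],
          config: TrainConfig) -> tuple[Trainer, list[LossReport]]:
    """Run the full protocol on ``dataset``; returns the trainer and history."""
    trainer = Trainer(config)
    history = trainer.fit(dataset)
    return trainer, history


def predict(trainer_or_path, images: np.ndarray,
            threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Inference from a live trainer or a checkpoint path."""
    trainer = trainer_or_path if isinstance(trainer_or_path, Trainer) \
        else load_checkpoint(trainer_or_path)
    return trainer.predict(images, threshold)


ABLATIONS = ("unet", "hed_unet", "gan", "gan_mb", "gan_mb_ir")
LOSS_ABLATIONS = ("la_lgs", "la_lds_lgs", "la_lds_lgs_lge")


def ablation_config(name: str, **overrides) -> TrainConfig:
    """Named architecture/loss configurations for the ablation matrix."""
    presets = {
        "unet": dict(adversarial=False, fusion="last", use_ir=False,
                     use_mb=False, use_lds=False, use_lge=False),
        "hed_unet": dict(adversarial=False, fusion="attention", use_ir=False,
                         use_mb=False, use_lds=True, use_lge=True),
        "gan": dict(adversarial=True, use_mb=False, use_ir=False),
        "gan_mb": dict(adversarial=True, use_mb=True, use_ir=False),
        "gan_mb_ir": dict(adversarial=True, use_mb=True, use_ir=True),
        # loss-combination ablations (on the full architecture)
        "la_lgs": dict(adversarial=True, use_lds=False, use_lge=False,
                       use_dice=True),
        "la_lds_lgs": dict(adversarial=True, use_lds=True, use_lge=False,
                           use_dice=True),
        "la_lds_lgs_lge": dict(adversarial=True, use_lds=True, use_lge=True,
                               use_dice=True),
    }
    if name not in presets:
        raise ConfigurationError(
            f"unknown ablation {name!r}; choose from {sorted(presets)}")
    fields = dict(presets[name])
    fields.update(overrides)
    return TrainConfig(**fields)
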