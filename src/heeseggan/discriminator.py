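"""Convolutional critic with feature matching and Gaussian-kernel
minibatch discrimination.

The critic scores the element-wise product of a composite and a mask
(predicted or ground truth).  Cross-sample similarity statistics computed
within a batch let it detect collapsed, overly similar generator outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import Tensor
from .nn import functional as F

__all__ = ["DiscriminatorConfig", "MinibatchState", "Discriminator",
           "minibatch_discrimination", "clip_weights", "build_discriminator"]


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 3
    widths: tuple[int, int, int, int] = (16, 32, 64, 128)
    dropout_rate: float = 0.20
    leaky_slope: float = 0.2
    input_size: int = 128
    mb_out_dim: int = 4
    mb_sigma_mode: Literal["as_printed", "fixed"] = "as_printed"
    mb_sigma_value: float = 1.0
    use_minibatch: bool = True
    clip_range: tuple[float, float] = (-0.012, 0.012)

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(
                f"dropout rate must be in [0, 1), got {self.dropout_rate}")
        lo, hi = self.clip_range
        if lo >= hi:
            raise ConfigurationError(f"clip range ({lo}, {hi}) must have lo < hi")
        if self.input_size % 16:
            raise ConfigurationError("input_size must be divisible by 16")


@dataclass
class MinibatchState:
    """Intermediate quantities of the minibatch-discrimination layer."""

    X: np.ndarray       # (b, n) input features
    Z: Tensor           # (b, k) projected features
    D: Tensor           # (b, b) squared distances, symmetric, zero diagonal
    K: Tensor           # (b, b) Gaussian similarities in (0, 1], unit diagonal
    M: Tensor           # (b,) mean similarity per sample
    sigma: float


def minibatch_sigma(n: int, k: int, mode: str = "as_printed",
                    value: float = 1.0) -> float:
    """Kernel bandwidth: the printed ``k/(2n)`` or a fixed override."""
    if mode == "as_printed":
        return k / (2.0 * n)
    if mode == "fixed":
        return value
    raise ConfigurationError(f"unknown sigma mode {mode!r}")


def minibatch_discrimination(X: Tensor | np.ndarray, W: Tensor | np.ndarray,
                             beta: Tensor | np.ndarray,
                             sigma: float) -> MinibatchState:
    """Project, compute pairwise squared distances, Gaussian similarities
    and the per-sample mean similarity vector."""
    X = nn.as_tensor(X)
    if not np.isfinite(X.data).all():
        raise FloatingPointError("non-finite values in minibatch features")
    W = nn.as_tensor(W)
    beta = nn.as_tensor(beta)
    b = X.shape[0]

    Z = X @ W + beta                                   # (b, k)
    sq = (Z * Z).sum(axis=1)                           # (b,)
    cross = Z @ Z.transpose(1, 0)                      # (b, b)
    D = (sq.reshape(b, 1) + sq.reshape(1, b) - 2.0 * cross).relu()
    D = D * Tensor(1.0 - np.eye(b))                    # exact zero diagonal
    # cap the exponent so K stays within (0, 1] instead of underflowing to 0
    cap = 700.0 * 2.0 * sigma ** 2
    D_capped = cap - (cap - D).relu()
    K = (-D_capped * (1.0 / (2.0 * sigma ** 2))).exp()
    M = K.mean(axis=1)
    return MinibatchState(X=X.data, Z=Z, D=D, K=K, M=M, sigma=float(sigma))


class Discriminator(nn.Module):
    """Four stride-2 conv stages, each conv + batch norm + LeakyReLU +
    dropout, followed by minibatch discrimination and a linear score head
    over pooled per-layer descriptors concatenated with the pooled input."""

    def __init__(self, config: DiscriminatorConfig,
                 rng: np.random.Generator | None = None,
                 dropout_rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        cin = config.in_channels
        layers = []
        for width in config.widths:
            layers.append(nn.Sequential(
                nn.Conv2d(cin, width, 3, stride=2, padding=1, rng=rng),
                nn.BatchNorm2d(width),
                nn.LeakyReLU(config.leaky_slope),
                nn.Dropout(config.dropout_rate, rng=dropout_rng)))
            cin = width
        self.stage1, self.stage2, self.stage3, self.stage4 = layers

        final_side = config.input_size // 16
        self.feature_dim = config.widths[3] * final_side * final_side
        if config.use_minibatch:
            self.mb_W = nn.Parameter(
                rng.normal(0, 0.02, (self.feature_dim, config.mb_out_dim)))
            self.mb_beta = nn.Parameter(np.zeros(config.mb_out_dim))
        head_dim = sum(config.widths) + config.in_channels \
            + (1 if config.use_minibatch else 0)
        self.head = nn.Linear(head_dim, 1, rng=rng)

    # -- pieces exposed for testing ---------------------------------------
    def trunk(self, x: Tensor | np.ndarray) -> tuple[list[Tensor], Tensor]:
        x = nn.as_tensor(x)
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ShapeError(f"spatial size {h}x{w} must be divisible by 16")
        feats = []
        cur = x
        for stage in (self.stage1, self.stage2, self.stage3, self.stage4):
            cur = stage(cur)
            feats.append(cur)
        return feats, cur.reshape(n, int(np.prod(cur.shape[1:])))

    def minibatch(self, X: Tensor) -> MinibatchState:
        sigma = minibatch_sigma(self.feature_dim, self.config.mb_out_dim,
                                self.config.mb_sigma_mode,
                                self.config.mb_sigma_value)
        return minibatch_discrimination(X, self.mb_W, self.mb_beta, sigma)

    def score(self, x: Tensor | np.ndarray) -> tuple[Tensor, Tensor, MinibatchState | None]:
        """Per-sample scores (b,), their batch mean, and the MB state."""
        x = nn.as_tensor(x)
        feats, flat = self.trunk(x)
        descriptor = [F.global_avg_pool(f) for f in feats]
        descriptor.append(F.global_avg_pool(x))
        state = None
        if self.config.use_minibatch:
            state = self.minibatch(flat)
            descriptor.append(state.M.reshape(x.shape[0], 1))
        scores = self.head(Tensor.concat(descriptor, axis=1))
        scores = scores.reshape(x.shape[0])
        return scores, scores.mean(), state

    def forward(self, x):
        return self.score(x)


def clip_weights(model: nn.Module,
                 clip_range: tuple[float, float] = (-0.012, 0.012)) -> nn.Module:
    """Clamp every trainable parameter into ``[lo, hi]`` in place."""
    lo, hi = clip_range
    if lo >= hi:
        raise ConfigurationError(f"clip range ({lo}, {hi}) must have lo < hi")
    for p in model.parameters():
        np.clip(p.data, lo, hi, out=p.data)
    return model


def build_discriminator(config: DiscriminatorConfig,
                        rng: np.random.Generator | None = None,
                        dropout_rng: np.random.Generator | None = None) -> Discriminator:
    return Discriminator(config, rng, dropout_rng)
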